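"""Search-pattern construction: PWM + base-pair constraints + conservation.

A :class:`TRProfile` is the statistical pattern used for structure-constrained
scanning: per-column residue frequencies (position weight matrix), a gap
frequency per column, the consensus pair table inherited from the alignment
structure line, and per-column conservation classes (invariant / >80%
conserved / variable) matching the convention used to annotate TR secondary
structure diagrams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .msa_io import (NESTED, PSEUDOKNOT, PairTable, StructuredAlignment)

RESIDUES = "ACGU"
_RES_INDEX = {r: k for k, r in enumerate(RESIDUES)}

INVARIANT = "invariant"
HIGH = "high"
VARIABLE = "variable"

#: default smoothing pseudocount per residue
DEFAULT_PSEUDOCOUNT = 0.5
#: strict conservation threshold: a column is "high" when a residue exceeds
#: this fraction of non-gap rows
CONSERVATION_THRESHOLD = 0.80
#: a column is treated as gap-dominated (unalignable) above this gap fraction
GAP_MAJORITY = 0.5


class ProfileError(ValueError):
    pass


@dataclass
class TRProfile:
    """PWM over {A,C,G,U} with gap frequencies, pairs and feature columns."""

    length: int
    col_freqs: np.ndarray          # (length, 4), rows sum to 1 - gap_freq
    gap_freq: np.ndarray           # (length,)
    pairs: PairTable
    background: np.ndarray         # (4,)
    pseudocount: float
    feature_cols: dict[str, tuple[int, int]] = field(default_factory=dict)
    conservation_class: list[str] = field(default_factory=list)
    pair_bonus: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.col_freqs = np.asarray(self.col_freqs, dtype=float)
        self.gap_freq = np.asarray(self.gap_freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.col_freqs.shape != (self.length, 4):
            raise ProfileError("col_freqs shape mismatch")
        if self.pseudocount < 0:
            raise ProfileError("pseudocount must be >= 0")
        total = self.col_freqs.sum(axis=1) + self.gap_freq
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ProfileError("column probabilities + gap frequency must sum to 1")
        for name, (a, b) in self.feature_cols.items():
            if not (0 <= a <= b <= self.length):
                raise ProfileError(f"feature {name!r} span ({a},{b}) out of range")

    def log_odds(self) -> np.ndarray:
        """(length, 5) log2(col_freq/background); 5th column (ambiguous) = 0.

        Residue probabilities are renormalised over non-gap mass so a fully
        conserved column scores the same whether or not other rows are gapped.
        """
        nongap = 1.0 - self.gap_freq
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(nongap[:, None] > 0, self.col_freqs / nongap[:, None], 0.25)
            lo = np.log2(np.maximum(p, 1e-12) / self.background[None, :])
        return np.hstack([lo, np.zeros((self.length, 1))])

    # -- serialization (structured text) ------------------------------------

    def to_json(self) -> str:
        payload = {
            "length": self.length,
            "residues": RESIDUES,
            "col_freqs": self.col_freqs.round(10).tolist(),
            "gap_freq": self.gap_freq.round(10).tolist(),
            "pairs": [
                {"i": i, "j": j, "layer": layer,
                 "name": self.pairs.element_names.get((i, j)),
                 "bonus": self.pair_bonus.get((i, j))}
                for i, j, layer in self.pairs
            ],
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "feature_cols": {k: list(v) for k, v in self.feature_cols.items()},
            "conservation_class": self.conservation_class,
        }
        return json.dumps(payload, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TRProfile":
        d = json.loads(text)
        names = {(p["i"], p["j"]): p["name"] for p in d["pairs"] if p.get("name")}
        bonus = {(p["i"], p["j"]): p["bonus"] for p in d["pairs"]
                 if p.get("bonus") is not None}
        pt = PairTable(frozenset((p["i"], p["j"], p["layer"]) for p in d["pairs"]),
                       element_names=names)
        return cls(
            length=d["length"],
            col_freqs=np.array(d["col_freqs"]),
            gap_freq=np.array(d["gap_freq"]),
            pairs=pt,
            background=np.array(d["background"]),
            pseudocount=d["pseudocount"],
            feature_cols={k: tuple(v) for k, v in d["feature_cols"].items()},
            conservation_class=list(d["conservation_class"]),
            pair_bonus=bonus,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TRProfile":
        return cls.from_json(Path(path).read_text())


def _column_counts(aln: StructuredAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Residue counts (n_cols, 4) and gap counts (n_cols,)."""
    counts = np.zeros((aln.n_cols, 4))
    gaps = np.zeros(aln.n_cols)
    for _, seq in aln.rows:
        for c, ch in enumerate(seq):
            k = _RES_INDEX.get(ch)
            if k is not None:
                counts[c, k] += 1
            elif ch == "-":
                gaps[c] += 1
            # ambiguity codes contribute to neither residues nor gaps
    return counts, gaps


def conservation_classes(aln: StructuredAlignment) -> list[str]:
    """Per-column class: invariant / high (>80% of non-gap rows) / variable.

    Gap-majority columns (>50% gaps) are always classed variable.
    """
    if aln.n_rows < 2:
        raise ProfileError("need at least 2 rows")
    counts, gaps = _column_counts(aln)
    classes = []
    for c in range(aln.n_cols):
        nongap = counts[c].sum()
        if nongap == 0 or gaps[c] / aln.n_rows > GAP_MAJORITY:
            classes.append(VARIABLE)
            continue
        top = counts[c].max() / nongap
        if top == 1.0:
            classes.append(INVARIANT)
        elif top > CONSERVATION_THRESHOLD:
            classes.append(HIGH)
        else:
            classes.append(VARIABLE)
    return classes


def build_profile(aln: StructuredAlignment,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  background: Optional[np.ndarray] = None,
                  feature_cols: Optional[dict[str, tuple[int, int]]] = None,
                  pair_bonus_canonical: float = 1.0,
                  ) -> TRProfile:
    """Estimate a :class:`TRProfile` from a structure-annotated alignment.

    Residue probabilities are smoothed counts over non-gap rows,
    ``(count + pc) / (n_nongap + 4 pc)``, scaled by the non-gap mass so each
    column's residue probabilities plus its gap frequency sum to one.  On a
    gap-free column this is exactly ``(count + pc) / (n_rows + 4 pc)``.
    """
    if aln.n_rows == 0:
        raise ProfileError("empty alignment")
    if aln.n_rows < 2:
        raise ProfileError("need at least 2 rows to estimate a profile")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    counts, gaps = _column_counts(aln)
    n_rows = aln.n_rows
    nongap = counts.sum(axis=1)
    gap_freq = gaps / n_rows
    denom = nongap + 4 * pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom[:, None] > 0, (counts + pseudocount) / denom[:, None], 0.25)
    col_freqs = p * (1.0 - gap_freq)[:, None]
    pairs = aln.pair_table()
    bonus = {(i, j): pair_bonus_canonical for i, j, _ in pairs}
    return TRProfile(
        length=aln.n_cols,
        col_freqs=col_freqs,
        gap_freq=gap_freq,
        pairs=pairs,
        background=background,
        pseudocount=pseudocount,
        feature_cols=dict(feature_cols or {}),
        conservation_class=conservation_classes(aln),
        pair_bonus=bonus,
    )


def consensus_sequence(profile: TRProfile) -> str:
    """Argmax residue per column (ties: A<C<G<U); gap-majority columns omitted."""
    out = []
    for c in range(profile.length):
        if profile.gap_freq[c] > GAP_MAJORITY:
            continue
        out.append(RESIDUES[int(np.argmax(profile.col_freqs[c]))])
    return "".join(out)
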