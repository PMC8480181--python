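"""Structure-annotated alignment and sequence I/O.

Telomerase RNA (TR) families are exchanged as Stockholm alignments whose
``#=GC SS_cons`` line carries a layered consensus structure: one nested
layer written with matching-type brackets (``<>``, ``()``, ``{}``, ``[]``)
plus up to four pseudoknot layers written ``Aa``–``Dd``.  The pseudoknot
layer is required for the TR template–pseudoknot domain, where helices P2b
and P3 cross.

Internally all coordinates are 0-based half-open; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NESTED = "nested"
PSEUDOKNOT = "pseudoknot"

#: bracket pairs treated as the nested layer (matched by type)
_NESTED_OPEN = {"<": ">", "(": ")", "{": "}", "[": "]"}
_NESTED_CLOSE = {v: k for k, v in _NESTED_OPEN.items()}
#: upper/lower letter pairs treated as pseudoknot layers
_PK_LETTERS = ("A", "B", "C", "D")

RNA_ALPHABET = frozenset("ACGU")
#: IUPAC ambiguity codes are legal input but unscorable (background-neutral)
AMBIGUITY = frozenset("NRYSWKMBDHV")

_RNA_COMP = str.maketrans("ACGUNRYSWKMBDHV-", "UGCANYRSWMKVHDB-")
_DNA_COMP = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


class MsaFormatError(ValueError):
    """Malformed alignment or structure annotation."""


def normalize_rna(seq: str) -> str:
    """Uppercase and map T->U (genome inputs are DNA)."""
    return seq.upper().replace("T", "U").replace(".", "-")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMP)[::-1]


@dataclass(frozen=True)
class PairTable:
    """Set of consensus base pairs ``(i, j, layer)`` with ``i < j``.

    Nested-layer pairs are mutually non-crossing; pseudoknot-layer pairs may
    cross nested ones.  ``element_names`` optionally maps a pair to a helix
    symbol (P1, P1.1, P2b, P3, P6.1, ...).
    """

    pairs: frozenset[tuple[int, int, str]]
    element_names: dict[tuple[int, int], str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j, layer in self.pairs:
            if not (0 <= i < j):
                raise MsaFormatError(f"invalid pair ({i},{j})")
            if layer not in (NESTED, PSEUDOKNOT):
                raise MsaFormatError(f"unknown layer {layer!r}")
            if i in seen or j in seen:
                raise MsaFormatError(f"column in more than one pair: ({i},{j})")
            seen.update((i, j))
        nested = sorted((i, j) for i, j, lay in self.pairs if lay == NESTED)
        for a, (i1, j1) in enumerate(nested):
            for i2, j2 in nested[a + 1:]:
                if i1 < i2 <= j1 < j2:
                    raise MsaFormatError(
                        f"crossing nested pairs ({i1},{j1}) and ({i2},{j2})")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    @property
    def nested(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, j, lay in self.pairs if lay == NESTED)

    @property
    def pseudoknot(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, j, lay in self.pairs if lay == PSEUDOKNOT)

    def partner_array(self, n_cols: int) -> list[int]:
        """Nested-layer partner per column (-1 if unpaired in that layer)."""
        pt = [-1] * n_cols
        for i, j in self.nested:
            if j >= n_cols:
                raise MsaFormatError(f"pair ({i},{j}) outside alignment of {n_cols} cols")
            pt[i], pt[j] = j, i
        return pt

    def helices(self) -> list[list[tuple[int, int]]]:
        """Group nested pairs into stems of consecutively stacked pairs."""
        stems: list[list[tuple[int, int]]] = []
        for i, j in self.nested:
            if stems and stems[-1][-1] == (i - 1, j + 1):
                stems[-1].append((i, j))
            else:
                stems.append([(i, j)])
        return stems


def brackets_to_pairtable(s: str) -> PairTable:
    """Convert a layered bracket string to a :class:`PairTable`.

    Matching-type brackets form the nested layer; ``Aa``–``Dd`` form
    pseudoknot layers.  Any other character (WUSS ``.,:_-~`` etc.) is
    unpaired.
    """
    pairs: set[tuple[int, int, str]] = set()
    stacks: dict[str, list[int]] = {k: [] for k in _NESTED_OPEN}
    pk_stacks: dict[str, list[int]] = {k: [] for k in _PK_LETTERS}
    for col, ch in enumerate(s):
        if ch in _NESTED_OPEN:
            stacks[ch].append(col)
        elif ch in _NESTED_CLOSE:
            opener = _NESTED_CLOSE[ch]
            if not stacks[opener]:
                raise MsaFormatError(f"unbalanced {ch!r} at column {col}")
            pairs.add((stacks[opener].pop(), col, NESTED))
        elif ch in _PK_LETTERS:
            pk_stacks[ch].append(col)
        elif ch.upper() in _PK_LETTERS and ch.islower():
            letter = ch.upper()
            if not pk_stacks[letter]:
                raise MsaFormatError(f"unbalanced {ch!r} at column {col}")
            pairs.add((pk_stacks[letter].pop(), col, PSEUDOKNOT))
    for opener, stack in stacks.items():
        if stack:
            raise MsaFormatError(f"unbalanced {opener!r} at column {stack[0]}")
    for letter, stack in pk_stacks.items():
        if stack:
            raise MsaFormatError(f"unbalanced {letter!r} at column {stack[0]}")
    return PairTable(frozenset(pairs))


def pairtable_to_brackets(pt: PairTable, n_cols: int) -> str:
    """Inverse of :func:`brackets_to_pairtable` (nested -> "()", PK -> "Aa"...)."""
    out = ["."] * n_cols
    for i, j in pt.nested:
        out[i], out[j] = "(", ")"
    # pseudoknot pairs are split greedily into mutually non-crossing groups,
    # one letter per group
    groups: list[list[tuple[int, int]]] = []
    for i, j in pt.pseudoknot:
        for grp in groups:
            if all(not (a < i <= b < j or i < a <= j < b) for a, b in grp):
                grp.append((i, j))
                break
        else:
            groups.append([(i, j)])
    if len(groups) > len(_PK_LETTERS):
        raise MsaFormatError("more pseudoknot layers than supported letters")
    for letter, grp in zip(_PK_LETTERS, groups):
        for i, j in grp:
            out[i], out[j] = letter, letter.lower()
    return "".join(out)


@dataclass
class StructuredAlignment:
    """Aligned RNA rows plus a layered consensus structure line."""

    rows: list[tuple[str, str]]
    consensus_structure: str
    group_labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_cols(self) -> int:
        return len(self.consensus_structure)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def taxon_ids(self) -> list[str]:
        return [tid for tid, _ in self.rows]

    def validate(self) -> None:
        ids = [tid for tid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({t for t in ids if ids.count(t) > 1})
            raise MsaFormatError(f"duplicate taxon ids: {dup}")
        n = self.n_cols
        for tid, seq in self.rows:
            if len(seq) != n:
                raise MsaFormatError(
                    f"row {tid!r} has length {len(seq)}, expected {n} "
                    "(structure line length)")
            bad = set(seq) - RNA_ALPHABET - AMBIGUITY - {"-"}
            if bad:
                raise MsaFormatError(f"row {tid!r} has invalid residues {sorted(bad)}")
        brackets_to_pairtable(self.consensus_structure)  # raises if unbalanced

    def pair_table(self) -> PairTable:
        return brackets_to_pairtable(self.consensus_structure)

    def column(self, c: int) -> list[str]:
        return [seq[c] for _, seq in self.rows]

    def with_row(self, taxon_id: str, aligned_seq: str) -> "StructuredAlignment":
        return StructuredAlignment(
            rows=self.rows + [(taxon_id, aligned_seq)],
            consensus_structure=self.consensus_structure,
            group_labels=dict(self.group_labels) if self.group_labels else None,
        )


# ---------------------------------------------------------------------------
# Stockholm
# ---------------------------------------------------------------------------

def read_stockholm(path: str | Path) -> StructuredAlignment:
    """Read one Stockholm alignment with a ``#=GC SS_cons`` structure line.

    Residues are normalised to the RNA alphabet (T mapped to U, ``.`` gaps
    to ``-``, uppercase).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        _raise_naming_ragged_row(path, exc)
        raise
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise MsaFormatError(f"{path}: no #=GC SS_cons structure line")
    rows = [(rec.id, normalize_rna(str(rec.seq))) for rec in aln]
    return StructuredAlignment(rows=rows, consensus_structure=ss)


def _raise_naming_ragged_row(path: Path, exc: Exception) -> None:
    """Best-effort re-parse to name the offending row of a ragged alignment."""
    lengths: dict[str, int] = {}
    try:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "//")):
                continue
            name, _, seq = line.partition(" ")
            lengths[name] = lengths.get(name, 0) + len(seq.split()[-1]) if seq.strip() else 0
    except Exception:
        return
    if lengths:
        most = max(lengths.values())
        bad = [n for n, ln in lengths.items() if ln != most]
        if bad:
            raise MsaFormatError(
                f"{path}: ragged alignment, offending row(s): {bad}") from exc


def write_stockholm(aln: StructuredAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(t) for t, _ in aln.rows) if aln.rows else 10
        width = max(width, len("#=GC SS_cons"))
        for tid, seq in aln.rows:
            fh.write(f"{tid:<{width}} {seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}} {aln.consensus_structure}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercase sequence)``; empty file -> [].

    Duplicate ids are disambiguated with ``.2``, ``.3``, ... suffixes and a
    warning.
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            warnings.warn(f"duplicate FASTA id {rid!r}; renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 1
        records.append((rid, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(seq_records)
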