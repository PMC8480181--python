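"""Ground-truthed synthetic TR families and genomes.

Generates telomerase-RNA-like sequence families with the conserved
architecture used throughout the toolkit: a template complementary to
1.5-2 tandem copies of the telomere repeat, a template-adjacent P1.1-type
stem (the TBE), a P2b/P3 pseudoknot (second pairing layer), a CR4/5-like
stem with a P6.1 terminal stem-loop, and a 3' box H/ACA domain (two
hairpins, an ANANNA H box in the hinge, an ACA trinucleotide 3 nt from the
3' end).  The ancestor is evolved down a user-supplied tree under a
Jukes-Cantor-like substitution model in which paired sites co-evolve: with
probability ``compensatory_prob`` a pair is "locked" on an edge and changes
only through compensatory double substitutions that preserve Watson-Crick
pairing.  Functional motif columns (template, H box, ACA box) are held
invariant, mirroring the invariant residues of real TR alignments.  Leaves
can then be planted into random genomic background, giving exact
coordinates for benchmarking the scanner and annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import dendropy

from .msa_io import NESTED, PSEUDOKNOT, PairTable, StructuredAlignment, \
    brackets_to_pairtable, revcomp_rna
from .primer_extension import template_for_repeat
from .tr_annotate import ACA_TAIL, P11_TYPE, TRAnnotation

RESIDUES = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: default H box instance (fits the ANANNA consensus)
DEFAULT_H_BOX = "AGAGUA"

#: substitution probability cap per edge (model breaks down beyond this)
MAX_EDGE_P = 0.75


class SpecError(ValueError):
    pass


def default_tr_structure(repeat_unit: str = "TTAGGG",
                         template_copies: float = 11 / 6,
                         n_spacer_stems: int = 0,
                         ) -> tuple[str, dict[str, tuple[int, int]], dict]:
    """Build the default TR-like architecture.

    ``n_spacer_stems`` adds that many accessory stem-loops between the
    CR4/5-like domain and the 3' H/ACA domain, emulating the large size
    variation of real TRs without touching the core features.  Returns
    ``(bracket_string, feature_spans, element_names)`` where
    ``element_names`` maps nested/PK pairs to helix symbols.
    """
    n_t = int(round(template_copies * len(repeat_unit)))
    parts: list[tuple[str, Optional[str]]] = [
        ("....", None),
        ("(" * 5, "P1.1_5p"),
        ("....", None),
        (")" * 5, "P1.1_3p"),
        (".", None),
        ("." * n_t, "template"),
        ("...", None),
        ("(" * 4, "P2b_5p"),
        ("..", None),
        ("A" * 4, "P3_5p"),
        ("..", None),
        (")" * 4, "P2b_3p"),
        ("...", None),
        ("a" * 4, "P3_3p"),
        ("...", None),
        ("(" * 4, "P6_5p"),
        ("..", None),
        ("(" * 4, "P6.1_5p"),
        ("....", None),
        (")" * 4, "P6.1_3p"),
        ("..", None),
        (")" * 4, "P6_3p"),
    ]
    for _k in range(n_spacer_stems):
        parts += [("...", None),
                  ("(" * 6 + "...." + ")" * 6, None),
                  ("...", None)]
    parts += [
        ("...", None),
        ("(" * 6 + "...." + ")" * 6, "P7a"),
        (".", None),
        ("." * len(DEFAULT_H_BOX), "H_box"),
        (".", None),
        ("(" * 6 + "...." + ")" * 6, "P8"),
        ("...", "ACA_box"),
        ("...", None),
    ]
    structure = ""
    features: dict[str, tuple[int, int]] = {}
    labelled_spans: list[tuple[str, int, int]] = []
    for frag, name in parts:
        a = len(structure)
        structure += frag
        if name in ("template", "H_box", "ACA_box"):
            features[name] = (a, a + len(frag))
        elif name is not None:
            labelled_spans.append((name.split("_")[0], a, a + len(frag)))
    pt = brackets_to_pairtable(structure)
    names: dict[tuple[int, int], str] = {}
    for i_, j_ in pt.nested:
        for symbol, a, b in labelled_spans:
            if a <= i_ < b:
                names[(i_, j_)] = symbol
                break
    for i_, j_ in pt.pseudoknot:
        names[(i_, j_)] = "P3"
    return structure, features, names


@dataclass
class FamilySpec:
    """Parameters of a synthetic TR family."""

    repeat_unit: str = "TTAGGG"
    template_copies: float = 11 / 6
    tree: str = "((A:1,B:1):1,(C:1,D:1):1);"
    subst_rate: float = 0.10
    compensatory_prob: float = 0.9
    indel_rate: float = 0.01
    seed: int = 0
    n_spacer_stems: int = 0
    structure: Optional[str] = None
    feature_cols: Optional[dict[str, tuple[int, int]]] = None
    element_names: Optional[dict[tuple[int, int], str]] = None
    h_box_seq: str = DEFAULT_H_BOX

    def __post_init__(self) -> None:
        if not 1.5 <= self.template_copies <= 2.0:
            raise SpecError("template_copies must lie in [1.5, 2.0]")
        for name, p in (("compensatory_prob", self.compensatory_prob),
                        ("indel_rate", self.indel_rate)):
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{name} must be a probability")
        if self.structure is None:
            s, f, n = default_tr_structure(self.repeat_unit, self.template_copies,
                                           self.n_spacer_stems)
            self.structure, self.feature_cols, self.element_names = s, f, n
        if self.feature_cols is None:
            raise SpecError("custom structure requires feature_cols")
        self._validate_features()

    def _validate_features(self) -> None:
        missing: list[str] = []
        pt = brackets_to_pairtable(self.structure)
        feats = self.feature_cols
        if "template" not in feats:
            missing.append("template span")
        else:
            t5 = feats["template"][0]
            near = any(
                span[1] <= t5 and t5 - span[1] <= 3
                for stem in pt.helices()
                for span in ((min(j for _, j in stem), max(j for _, j in stem) + 1),
                             (min(i for i, _ in stem), max(i for i, _ in stem) + 1)))
            if not near:
                missing.append("template-adjacent stem (TBE)")
        if not pt.pseudoknot:
            missing.append("pseudoknot pair layer")
        outer = []
        for stem in pt.helices():
            i = min(i for i, _ in stem)
            j = max(j for _, j in stem) + 1
            outer.append((i, j))
        outer = sorted(s for s in outer
                       if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                                  for o in outer))
        if len(outer) < 2 or ("H_box" in feats and not (
                outer[-2][1] <= feats["H_box"][0]
                and feats["H_box"][1] <= outer[-1][0])):
            missing.append("two 3' hairpins with an H-box hinge")
        if "H_box" not in feats:
            missing.append("H box")
        if "ACA_box" not in feats:
            missing.append("ACA box")
        else:
            a, b = feats["ACA_box"]
            if len(self.structure) - b != ACA_TAIL:
                missing.append(f"ACA box ending {ACA_TAIL} nt before the 3' end")
        if missing:
            raise SpecError("structure lacks required TR features: "
                            + "; ".join(missing))

    @property
    def length(self) -> int:
        return len(self.structure)

    def pair_table(self) -> PairTable:
        pt = brackets_to_pairtable(self.structure)
        return PairTable(pt.pairs, element_names=dict(self.element_names or {}))


@dataclass
class SyntheticLeaf:
    name: str
    seq: str                       # unaligned leaf sequence
    aligned: str                   # over ancestor match columns ('-' = deleted)
    pair_table: PairTable          # structure in leaf coordinates
    annotation: TRAnnotation       # ground truth
    col_map: list[Optional[int]]   # ancestor column -> leaf position


@dataclass
class SyntheticFamily:
    spec: FamilySpec
    ancestor: str
    leaves: dict[str, SyntheticLeaf]
    planting: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["genome_id", "leaf", "start", "end", "strand"]))

    def to_alignment(self) -> StructuredAlignment:
        return StructuredAlignment(
            rows=[(leaf.name, leaf.aligned) for leaf in self.leaves.values()],
            consensus_structure=self.spec.structure)


def _build_ancestor(spec: FamilySpec, rng: np.random.Generator) -> str:
    L = spec.length
    seq = [RESIDUES[k] for k in rng.integers(0, 4, size=L)]
    pt = spec.pair_table()
    for i, j, _layer in pt:
        left = RESIDUES[int(rng.integers(0, 4))]
        seq[i], seq[j] = left, _WC[left]
    t_lo, t_hi = spec.feature_cols["template"]
    template = template_for_repeat(spec.repeat_unit, spec.template_copies)
    if len(template) != t_hi - t_lo:
        raise SpecError("template span does not fit the requested copy number")
    seq[t_lo:t_hi] = list(template)
    # boundary guards: the residues flanking the template must break the
    # telomeric periodicity, or the template span would be ambiguous
    periodic = revcomp_rna(spec.repeat_unit * 10)
    k = periodic.index(template, 1)
    paired = {c for i, j, _l in pt for c in (i, j)}
    for col, bad in ((t_lo - 1, periodic[k - 1]),
                     (t_hi, periodic[k + len(template)])):
        if 0 <= col < L and col not in paired:
            choices = [r for r in RESIDUES if r != bad]
            seq[col] = choices[int(rng.integers(0, len(choices)))]
    h_lo, h_hi = spec.feature_cols["H_box"]
    seq[h_lo:h_hi] = list(spec.h_box_seq)
    a_lo, a_hi = spec.feature_cols["ACA_box"]
    seq[a_lo:a_hi] = list("ACA")
    return "".join(seq)


def _frozen_columns(spec: FamilySpec) -> set[int]:
    frozen: set[int] = set()
    for span in spec.feature_cols.values():
        frozen.update(range(*span))
    # the template boundary guards stay frozen so the ground-truth span
    # remains the unique longest complementary stretch in every leaf
    t_lo, t_hi = spec.feature_cols["template"]
    frozen.update(c for c in (t_lo - 1, t_hi) if 0 <= c < spec.length)
    return frozen


def _evolve_edge(cells: list[str], spec: FamilySpec, p_sub: float,
                 rng: np.random.Generator) -> list[str]:
    """One edge of evolution on per-column cells ('' = deleted, len>1 = insert)."""
    pt = spec.pair_table()
    frozen = _frozen_columns(spec)
    L = spec.length
    paired_cols = set()
    out = list(cells)

    def mutate(ch: str) -> str:
        alts = [r for r in RESIDUES if r != ch]
        return alts[int(rng.integers(0, 3))]

    for i, j, _layer in pt:
        paired_cols.update((i, j))
        if not out[i] or not out[j]:
            continue  # a deleted strand no longer co-evolves
        locked = rng.random() < spec.compensatory_prob
        if locked:
            if rng.random() < p_sub:
                new_left = mutate(out[i][0])
                out[i] = new_left + out[i][1:]
                out[j] = _WC[new_left] + out[j][1:]
        else:
            for c in (i, j):
                if rng.random() < p_sub:
                    out[c] = mutate(out[c][0]) + out[c][1:]
    for c in range(L):
        if c in paired_cols or c in frozen or not out[c]:
            continue
        if rng.random() < p_sub:
            out[c] = mutate(out[c][0]) + out[c][1:]
    if spec.indel_rate > 0:
        tail_guard = set(range(L - ACA_TAIL - 3, L))
        for c in range(L):
            if c in paired_cols or c in frozen or c in tail_guard or not out[c]:
                continue
            if rng.random() < spec.indel_rate:
                if rng.random() < 0.5:
                    out[c] = ""  # deletion of a loop residue
                else:
                    out[c] = out[c] + RESIDUES[int(rng.integers(0, 4))]
    return out


def _cells_to_leaf(name: str, cells: list[str], spec: FamilySpec,
                   ) -> SyntheticLeaf:
    col_map: list[Optional[int]] = []
    seq_parts: list[str] = []
    pos = 0
    for cell in cells:
        if cell == "":
            col_map.append(None)
        else:
            col_map.append(pos)
            pos += len(cell)
        seq_parts.append(cell)
    seq = "".join(seq_parts)
    aligned = "".join(cell[0] if cell else "-" for cell in cells)
    pt = spec.pair_table()
    shifted = set()
    names: dict[tuple[int, int], str] = {}
    for i, j, layer in pt:
        li, lj = col_map[i], col_map[j]
        if li is None or lj is None:
            continue
        shifted.add((li, lj, layer))
        sym = (spec.element_names or {}).get((i, j))
        if sym:
            names[(li, lj)] = sym
    leaf_pt = PairTable(frozenset(shifted), element_names=names)

    def span(feature: str) -> tuple[int, int]:
        a, b = spec.feature_cols[feature]
        return col_map[a], col_map[b - 1] + 1

    t_span = span("template")
    ann = TRAnnotation(
        template_span=t_span,
        template_seq=seq[t_span[0]:t_span[1]],
        repeat_unit=spec.repeat_unit,
        tbe_type=P11_TYPE,
        h_box=span("H_box"),
        aca_box=span("ACA_box"),
        three_prime_end=len(seq),
        elements={sym: True for sym in set(names.values())},
    )
    ann.validate()
    return SyntheticLeaf(name=name, seq=seq, aligned=aligned,
                         pair_table=leaf_pt, annotation=ann, col_map=col_map)


def sample_family(spec: FamilySpec) -> SyntheticFamily:
    """Evolve a ground-truthed family down the spec's tree (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    ancestor = _build_ancestor(spec, rng)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick")
    cells_at: dict = {tree.seed_node: [ch for ch in ancestor]}
    leaves: dict[str, SyntheticLeaf] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge_len = node.edge.length if node.edge.length is not None else 1.0
        p_sub = min(spec.subst_rate * edge_len, MAX_EDGE_P)
        cells_at[node] = _evolve_edge(cells_at[node.parent_node], spec,
                                      p_sub, rng)
        if node.is_leaf():
            name = node.taxon.label if node.taxon else f"leaf{len(leaves)}"
            leaves[name] = _cells_to_leaf(name, cells_at[node], spec)
    return SyntheticFamily(spec=spec, ancestor=ancestor, leaves=leaves)


# ---------------------------------------------------------------------------
# genome planting
# ---------------------------------------------------------------------------

#: default first-order Markov background: mild same-nucleotide persistence
DEFAULT_MARKOV = np.array([
    [0.32, 0.20, 0.24, 0.24],
    [0.26, 0.30, 0.18, 0.26],
    [0.24, 0.26, 0.30, 0.20],
    [0.22, 0.24, 0.26, 0.28],
])

_DNA = "ACGT"


def _background(length: int, kind: str, rng: np.random.Generator,
                markov: Optional[np.ndarray] = None) -> str:
    if kind == "iid":
        return "".join(_DNA[k] for k in rng.integers(0, 4, size=length))
    if kind == "markov1":
        P = DEFAULT_MARKOV if markov is None else np.asarray(markov, float)
        P = P / P.sum(axis=1, keepdims=True)
        out = np.empty(length, dtype=np.int64)
        out[0] = rng.integers(0, 4)
        for t in range(1, length):
            out[t] = rng.choice(4, p=P[out[t - 1]])
        return "".join(_DNA[k] for k in out)
    raise ValueError(f"unknown background kind {kind!r}")


def plant(family: SyntheticFamily, genome_length: int,
          background: str = "iid",
          positions: Optional[dict[str, int]] = None,
          strands: Optional[dict[str, str]] = None,
          seed: int = 0,
          markov: Optional[np.ndarray] = None,
          ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Embed each leaf in its own random genome (one TR gene per genome).

    Returns FASTA-style records and a truth table with exact coordinates
    (0-based half-open, forward strand).  Reverse-strand plantings insert
    the reverse complement.
    """
    from .msa_io import revcomp_dna

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    rows = []
    for name, leaf in family.leaves.items():
        insert = leaf.seq.replace("U", "T")
        if len(insert) > genome_length:
            raise ValueError(f"leaf {name!r} longer than genome_length")
        gid = f"{name}_genome"
        g = _background(genome_length, background, rng, markov)
        pos = (positions or {}).get(name)
        if pos is None:
            pos = int(rng.integers(0, genome_length - len(insert) + 1))
        if pos + len(insert) > genome_length:
            raise ValueError(f"planting of {name!r} overflows the genome")
        strand = (strands or {}).get(name, "+")
        payload = insert if strand == "+" else revcomp_dna(insert)
        g = g[:pos] + payload + g[pos + len(insert):]
        records.append((gid, g))
        rows.append({"genome_id": gid, "leaf": name, "start": pos,
                     "end": pos + len(insert), "strand": strand})
    return records, pd.DataFrame(rows)


def divergence(a: str, b: str) -> float:
    """Per-site difference fraction between two equal-length gapless strings."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x != y for x, y in pairs) / len(pairs)
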