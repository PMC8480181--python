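"""Covariation and conservation support for proposed helices.

Comparative support for a base pair comes from coordinated substitutions
that preserve canonical (Watson-Crick or G.U) pairing: a pair is called
*covarying* when at least two distinct canonical pair identities are
observed across the alignment and at most a small fraction of rows pair
noncanonically.  Support can be computed over the whole alignment
("universal" covariations) or within labelled clades ("group-specific"
covariations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .msa_io import PairTable, StructuredAlignment
from .profile_model import conservation_classes

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
RESIDUES = "ACGU"

#: maximum tolerated fraction of noncanonical rows for a covarying call
MAX_NONCANONICAL_FRAC = 0.1


@dataclass
class PairSupport:
    i: int
    j: int
    layer: str
    n_rows_canonical: int
    n_rows_noncanonical: int
    n_pair_types: int
    mutual_information: float
    covarying: bool
    insufficient_data: bool
    scope: str = "universal"

    @property
    def n_informative(self) -> int:
        return self.n_rows_canonical + self.n_rows_noncanonical


@dataclass
class CovariationReport:
    pairs: list[PairSupport]
    conservation_class: list[str]
    scope: str = "universal"

    def by_pair(self) -> dict[tuple[int, int], PairSupport]:
        return {(p.i, p.j): p for p in self.pairs}


def mutual_information(col_a: list[str], col_b: list[str]) -> float:
    """Base-2 mutual information between two columns over non-gap rows."""
    rows = [(a, b) for a, b in zip(col_a, col_b)
            if a in RESIDUES and b in RESIDUES]
    n = len(rows)
    if n == 0:
        return 0.0
    joint: dict[tuple[str, str], int] = {}
    pa: dict[str, int] = {}
    pb: dict[str, int] = {}
    for a, b in rows:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pa[a] = pa.get(a, 0) + 1
        pb[b] = pb.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((pa[a] / n) * (pb[b] / n)))
    return max(mi, 0.0)


def pair_support(aln: StructuredAlignment, pairtable: PairTable,
                 max_noncanonical_frac: float = MAX_NONCANONICAL_FRAC,
                 scope: str = "universal") -> CovariationReport:
    """Count canonical/noncanonical rows and call covariation per pair.

    Rows with a gap at either position are excluded from that pair's
    counts.  A pair with fewer than two informative rows is flagged
    ``insufficient_data`` and never called covarying.
    """
    supports = []
    for i, j, layer in pairtable:
        if j >= aln.n_cols:
            raise ValueError(f"pair ({i},{j}) outside alignment")
        col_i, col_j = aln.column(i), aln.column(j)
        types: set[tuple[str, str]] = set()
        n_canon = n_noncanon = 0
        for a, b in zip(col_i, col_j):
            if a not in RESIDUES or b not in RESIDUES:
                continue
            if (a, b) in CANONICAL:
                n_canon += 1
                types.add((a, b))
            else:
                n_noncanon += 1
        informative = n_canon + n_noncanon
        insufficient = informative < 2
        frac_noncanon = (n_noncanon / informative) if informative else 1.0
        covarying = (not insufficient and len(types) >= 2
                     and frac_noncanon <= max_noncanonical_frac)
        supports.append(PairSupport(
            i=i, j=j, layer=layer,
            n_rows_canonical=n_canon,
            n_rows_noncanonical=n_noncanon,
            n_pair_types=len(types),
            mutual_information=mutual_information(col_i, col_j),
            covarying=covarying,
            insufficient_data=insufficient,
            scope=scope,
        ))
    return CovariationReport(pairs=supports,
                             conservation_class=conservation_classes(aln),
                             scope=scope)


def group_support(aln: StructuredAlignment, pairtable: PairTable,
                  max_noncanonical_frac: float = MAX_NONCANONICAL_FRAC,
                  ) -> dict[str, CovariationReport]:
    """Per-group covariation reports plus the universal report.

    Requires ``aln.group_labels`` covering every row.  Groups with fewer
    than two rows are skipped with a warning.  The returned dict maps
    ``"universal"`` and ``"group:<name>"`` to reports.
    """
    if not aln.group_labels:
        raise ValueError("alignment has no group labels")
    missing = [t for t in aln.taxon_ids if t not in aln.group_labels]
    if missing:
        raise ValueError(f"rows without group label: {missing}")
    out = {"universal": pair_support(aln, pairtable, max_noncanonical_frac)}
    groups: dict[str, list[tuple[str, str]]] = {}
    for tid, seq in aln.rows:
        groups.setdefault(aln.group_labels[tid], []).append((tid, seq))
    for name in sorted(groups):
        rows = groups[name]
        if len(rows) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 rows; skipped")
            continue
        sub = StructuredAlignment(rows=rows,
                                  consensus_structure=aln.consensus_structure)
        out[f"group:{name}"] = pair_support(
            sub, pairtable, max_noncanonical_frac, scope=f"group:{name}")
    return out


def classify_scopes(reports: dict[str, CovariationReport],
                    ) -> dict[tuple[int, int], list[str]]:
    """Scope of each covarying pair: universal beats group-specific calls."""
    out: dict[tuple[int, int], list[str]] = {}
    universal = reports.get("universal")
    for scope, rep in reports.items():
        for p in rep.pairs:
            key = (p.i, p.j)
            out.setdefault(key, [])
            if universal is not None and universal.by_pair()[key].covarying:
                out[key] = ["universal"]
            elif scope != "universal" and p.covarying and out[key] != ["universal"]:
                out[key].append(scope)
    return out


def covariation_table(reports: dict[str, CovariationReport] | CovariationReport,
                      ) -> str:
    """Tab-delimited covariation table (1-based column coordinates)."""
    if isinstance(reports, CovariationReport):
        reports = {reports.scope: reports}
    lines = ["\t".join(["scope", "i", "j", "layer", "n_canonical",
                        "n_noncanonical", "n_pair_types", "MI_bits",
                        "covarying", "insufficient_data"])]
    for scope, rep in reports.items():
        for p in rep.pairs:
            lines.append("\t".join(map(str, [
                scope, p.i + 1, p.j + 1, p.layer, p.n_rows_canonical,
                p.n_rows_noncanonical, p.n_pair_types,
                f"{p.mutual_information:.4f}", p.covarying,
                p.insufficient_data])))
    return "\n".join(lines) + "\n"


def annotate_structure_string(structure: str, report: CovariationReport) -> str:
    """Upper-case covarying pair positions in a bracket string copy."""
    out = list(structure.lower())
    for p in report.pairs:
        if p.covarying:
            out[p.i] = structure[p.i].upper()
            out[p.j] = structure[p.j].upper()
    return "".join(out)
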