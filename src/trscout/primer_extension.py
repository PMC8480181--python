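"""In silico telomerase primer-extension assay.

Simulates the direct primer-extension readout used to validate candidate
telomerase RNAs: a telomeric DNA primer anneals to the RNA template, the
enzyme copies the template up to its 5' boundary (first pass), then
translocates and adds further telomeric repeats with probability *p* per
repeat (repeat-addition processivity), producing the characteristic ladder
with increments equal to the repeat-unit length.  Circularly permuted
primers phase the annealing register and shift the first-stop product by one
nucleotide per permutation.  A template-boundary-element (TBE) model
predicts read-through for insertions placed between the template and the
TBE anchor, and an intact boundary for insertions elsewhere (the classic
L1/L2 insertion-mutant contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .msa_io import revcomp_rna

_DNA_TO_RNA_PAIR = {"A": "U", "C": "G", "G": "C", "T": "A"}

#: minimum primer 3' suffix that must base-pair for productive annealing
MIN_ANNEAL = 3


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class TemplateSpec:
    """Template geometry in full-TR 1-based coordinates.

    ``template_start`` is the 1-based position of the template 5' boundary;
    ``boundary_anchor_offset`` is the number of nucleotides between that
    boundary and the 3' end of the TBE anchor strand (0 for an intact
    template-adjacent P1.1-type stem).  ``insertion`` is an optional
    ``(position, residues)`` mutation, inserted immediately *after* the
    1-based position (the L1/L2 convention).
    """

    template: str
    template_start: int = 1
    boundary_anchor_offset: int = 0
    insertion: Optional[tuple[int, str]] = None

    def __post_init__(self) -> None:
        if not self.template:
            raise AssayError("template must be non-empty")
        if self.template_start < 1:
            raise AssayError("template_start is 1-based, must be >= 1")
        if self.boundary_anchor_offset < 0:
            raise AssayError("boundary_anchor_offset must be >= 0")
        if self.insertion is not None and self.insertion[0] < 1:
            raise AssayError("insertion position is 1-based, must be >= 1")


@dataclass(frozen=True)
class LadderProfile:
    """Predicted extension products: lengths (nt) and relative intensities."""

    bands: tuple[tuple[int, float], ...]
    repeat_unit_length: int
    first_stop_length: int

    def __post_init__(self) -> None:
        lengths = [b[0] for b in self.bands]
        if lengths != sorted(set(lengths)):
            raise AssayError("band lengths must be strictly increasing")
        intens = [b[1] for b in self.bands]
        if any(not (0 < x <= 1) for x in intens):
            raise AssayError("intensities must be in (0, 1]")
        if any(later > earlier for earlier, later in zip(intens, intens[1:])):
            raise AssayError("intensities must be non-increasing with length")


def anneal(template: str, primer: str) -> Optional[tuple[int, int]]:
    """Find the annealing register of a DNA primer on an RNA template.

    Returns ``(n_paired, pos)`` where ``n_paired`` is the length of the
    longest primer 3' suffix exactly Watson–Crick complementary (no G.U in
    the DNA:RNA hybrid) to a template substring, and ``pos`` is the 0-based
    template index paired with the primer's 3'-terminal nucleotide.  The
    duplex is antiparallel, so the primer suffix (5'->3') pairs the template
    substring read 3'->5': ``template[pos]`` pairs the primer 3' end.  Ties
    between equal-length registers resolve to the one closest to the
    template 3' end.  Returns None if no suffix of >= 3 nt anneals.
    """
    if len(primer) < MIN_ANNEAL:
        raise AssayError("primer must be at least 3 nt")
    template = template.upper().replace("T", "U")
    primer = primer.upper()
    best: Optional[tuple[int, int]] = None
    for k in range(MIN_ANNEAL, min(len(primer), len(template)) + 1):
        suffix = primer[-k:]
        # template region (5'->3') pairing the suffix is its reverse complement
        want = "".join(_DNA_TO_RNA_PAIR[b] for b in suffix[::-1])
        found = -1
        start = 0
        while True:
            idx = template.find(want, start)
            if idx < 0:
                break
            found = idx  # keep right-most register (closest to template 3' end)
            start = idx + 1
        if found >= 0:
            # want[0] = complement of the primer 3' nt, so the 3' terminus
            # pairs template[found]; synthesis copies template[found-1 .. 0]
            best = (k, found)
    return best


def first_pass(template: str, primer: str) -> Optional[int]:
    """Nucleotides added before the template 5' boundary stops synthesis.

    Extension copies the template from the register toward its 5' end, so
    the count equals the number of template residues 5' of the position
    paired with the primer 3' terminus.
    """
    reg = anneal(template, primer)
    if reg is None:
        return None
    _, pos = reg
    return pos


def circular_permutations(repeat_unit: str) -> list[str]:
    """All distinct rotations of the repeat unit (6 for TTAGGG)."""
    u = repeat_unit.upper()
    seen: list[str] = []
    for k in range(len(u)):
        rot = u[k:] + u[:k]
        if rot not in seen:
            seen.append(rot)
    return seen


def _min_period(s: str) -> int:
    """Smallest period of s (failure-function method)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1]


def ladder(template: str, primer: str, processivity: float,
           max_repeats: int, repeat_unit_length: Optional[int] = None,
           ) -> Optional[LadderProfile]:
    """Predict the repeat-addition ladder for one primer.

    Band *k* (k = 0..max_repeats) has length
    ``len(primer) + first_pass + k * u`` and relative intensity ``p**k``
    (band 0 normalised to 1); ``u`` defaults to the minimal period of the
    template, i.e. the telomeric repeat-unit length.
    """
    if not (0 <= processivity < 1):
        raise AssayError("processivity must be in [0, 1)")
    fp = first_pass(template, primer)
    if fp is None:
        return None
    u = repeat_unit_length if repeat_unit_length is not None else _min_period(
        template.upper().replace("T", "U"))
    first_len = len(primer) + fp
    n_bands = 1 if processivity == 0 else max_repeats + 1
    bands = tuple((first_len + k * u, processivity ** k) for k in range(n_bands))
    return LadderProfile(bands=bands, repeat_unit_length=u,
                         first_stop_length=first_len)


def template_for_repeat(repeat_unit: str, copies: float = 1.83,
                        phase: int = 0) -> str:
    """RNA template complementary to ~``copies`` tandem copies of the repeat.

    The template is the reverse complement (RNA alphabet) of a circularly
    permuted tandem extension of the DNA repeat unit, e.g. 1.83 copies of
    TTAGGG -> the 11-mer CUAACCCUAAC.
    """
    u = len(repeat_unit)
    n = int(round(copies * u))
    tandem = (repeat_unit * (n // u + 2))[phase:phase + n]
    return revcomp_rna(tandem.replace("T", "U"))


def boundary_readthrough(spec: TemplateSpec) -> tuple[Optional[bool], int]:
    """Predict TBE failure for an insertion mutant.

    An insertion strictly between the TBE anchor and the template 5'
    boundary pushes the boundary away from the anchor: the enzyme copies
    ``extra_nt = len(insertion)`` nucleotides beyond the original boundary
    (readthrough).  Insertions 5' of the anchor or 3' of the template leave
    the boundary intact.  Insertions inside the template itself alter the
    template and yield no boundary verdict (None).
    """
    if spec.insertion is None:
        return False, 0
    pos, residues = spec.insertion
    t5 = spec.template_start                      # 1-based template 5' boundary
    t3 = t5 + len(spec.template) - 1
    anchor_end = t5 - 1 - spec.boundary_anchor_offset  # last nt of anchor strand
    if t5 <= pos < t3:
        return None, 0  # template-altering, no boundary verdict
    if anchor_end <= pos < t5:
        return True, len(residues)
    return False, 0
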