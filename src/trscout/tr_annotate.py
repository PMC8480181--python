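"""Candidate telomerase-RNA annotation.

Locates the template (complementary to 1.5–2 tandem copies of the telomere
repeat), classifies the template boundary element (template-adjacent
P1.1-type stem vs linker-constrained upstream P1-type stem), finds the box
H/ACA biogenesis motifs (H box ANANNA in the hinge between the two 3'
hairpins; ACA trinucleotide ending exactly 3 nt before the mature 3' end),
assigns transcript ends (TATA-proximal 5' start, ACA+3 3' end) and flags
which named structural elements are realised.

Intervals are 0-based half-open internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .msa_io import PairTable, normalize_rna, revcomp_rna

#: H box consensus from the box H/ACA snoRNA literature (N = any residue)
H_BOX_CONSENSUS = "ANANNA"
#: CAB box consensus (scaRNA literature); lowercase = weakly constrained
CAB_BOX_CONSENSUS = "UGAG"
#: mature 3' end sits this many nt downstream of the ACA box
ACA_TAIL = 3
#: canonical TATA-box to transcription-start offset (core promoter spacing)
TATA_TSS_OFFSET = 25

P1_TYPE = "P1_type"
P11_TYPE = "P1.1_type"
TBE_NONE = "none"

ELEMENT_NAMES = ("P1", "P1.1", "P2", "P2a", "P2a.1", "P2.1", "P2b", "P3",
                 "P4", "P5", "P6", "P6.1", "P7a", "P8", "P8b",
                 "CR4/5", "eCR4/5", "H/ACA", "CAB")


@dataclass
class TRAnnotation:
    """Annotation of one TR candidate (coordinates on the candidate)."""

    template_span: Optional[tuple[int, int]] = None
    template_seq: Optional[str] = None
    repeat_unit: Optional[str] = None
    tbe_type: str = TBE_NONE
    tbe_anchor: Optional[tuple[int, int]] = None
    h_box: Optional[tuple[int, int]] = None
    aca_box: Optional[tuple[int, int]] = None
    cab_box: Optional[tuple[int, int]] = None
    five_prime_origin: str = "given"
    three_prime_rule: str = f"ACA+{ACA_TAIL}"
    three_prime_end: Optional[int] = None
    elements: dict[str, bool] = field(default_factory=dict)

    @property
    def template_u_ratio(self) -> Optional[float]:
        """Template length over repeat-unit length (the 1.5-2x copy number)."""
        if self.template_seq is None or not self.repeat_unit:
            return None
        return len(self.template_seq) / len(self.repeat_unit)

    def validate(self) -> None:
        if self.aca_box is not None and self.three_prime_end is not None:
            if self.aca_box[1] + ACA_TAIL != self.three_prime_end:
                raise ValueError(
                    f"ACA box {self.aca_box} does not end {ACA_TAIL} nt "
                    f"before the 3' end {self.three_prime_end}")


def find_template(seq: str, repeat_unit: str,
                  min_copies: float = 1.5, max_copies: float = 2.0,
                  max_mismatches: int = 0) -> Optional[tuple[int, int]]:
    """Locate the template: the longest stretch complementary to the repeat.

    Searches for the longest substring of ``seq`` equal (up to
    ``max_mismatches``) to a window of the reverse-complemented tandem
    telomere repeat, with length between ``ceil(min_copies*u)`` and
    ``floor(max_copies*u)``; leftmost on ties.  Returns the 0-based
    half-open span or None.
    """
    if len(repeat_unit) < 2:
        raise ValueError("repeat_unit must be >= 2 nt")
    seq = normalize_rna(seq)
    u = len(repeat_unit)
    lo = math.ceil(min_copies * u - 1e-9)
    hi = math.floor(max_copies * u + 1e-9)
    if hi < lo:
        return None
    # every qualifying template is a window of the periodic complement string
    periodic = revcomp_rna(repeat_unit * (hi // u + 3))
    for L in range(min(hi, len(seq)), lo - 1, -1):
        windows = {periodic[k:k + L] for k in range(u)}
        for i in range(len(seq) - L + 1):
            frag = seq[i:i + L]
            if max_mismatches == 0:
                if frag in windows:
                    return (i, i + L)
            else:
                if any(sum(a != b for a, b in zip(frag, w)) <= max_mismatches
                       for w in windows):
                    return (i, i + L)
    return None


def classify_tbe(seq: str, structure: PairTable,
                 template_span: tuple[int, int],
                 max_gap: int = 3) -> tuple[str, Optional[tuple[int, int]]]:
    """Classify the template boundary element.

    ``P1.1_type``: a stem strand ends within ``max_gap`` nt of the template
    5' boundary (template-adjacent stem).  ``P1_type``: the nearest upstream
    stem is farther away (boundary set by the linker length instead).
    ``none``: no stem 5' of the template.  Returns the type and the 0-based
    span of the anchoring stem strand.
    """
    t5 = template_span[0]
    best: Optional[tuple[int, tuple[int, int]]] = None  # (distance, strand span)
    for stem in structure.helices():
        # each stem has a 5' strand (i side) and a 3' strand (j side); either
        # can be the template-adjacent anchor as long as it lies upstream
        i_lo = min(i for i, _ in stem)
        i_hi = max(i for i, _ in stem) + 1
        j_lo = min(j for _, j in stem)
        j_hi = max(j for _, j in stem) + 1
        for span in ((i_lo, i_hi), (j_lo, j_hi)):
            if span[1] <= t5:
                dist = t5 - span[1]
                if best is None or dist < best[0]:
                    best = (dist, span)
    if best is None:
        return TBE_NONE, None
    dist, span = best
    return (P11_TYPE if dist <= max_gap else P1_TYPE), span


def _hairpins(structure: PairTable) -> list[tuple[int, int]]:
    """Outermost span of each hairpin-forming stem, 5' to 3'."""
    spans = []
    for stem in structure.helices():
        i = min(i for i, _ in stem)
        j = max(j for _, j in stem) + 1
        spans.append((i, j))
    # keep only outermost (not nested inside another stem span)
    outer = [s for s in spans
             if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)]
    return sorted(outer)


def match_consensus(window: str, consensus: str) -> bool:
    """Does a window match an IUPAC-ish consensus (N matches anything)?"""
    if len(window) != len(consensus):
        return False
    return all(c == "N" or w == c for w, c in zip(window, consensus.upper()))


def find_haca_boxes(seq: str, structure: Optional[PairTable] = None,
                    h_consensus: str = H_BOX_CONSENSUS,
                    ) -> tuple[Optional[tuple[int, int]], Optional[tuple[int, int]]]:
    """Locate the H box and the ACA box of the 3' H/ACA domain.

    The ACA box is the trinucleotide ``ACA`` ending exactly ``ACA_TAIL`` nt
    before the sequence 3' end.  The H box is the 5'-most window matching
    the consensus (default ANANNA) inside the single-stranded hinge between
    the two 3'-domain hairpins; without a structure the whole sequence is
    searched.
    """
    if len(seq) < 10:
        raise ValueError("sequence too short for H/ACA annotation")
    seq = normalize_rna(seq)
    n = len(seq)
    aca = None
    if seq[n - ACA_TAIL - 3:n - ACA_TAIL] == "ACA":
        aca = (n - ACA_TAIL - 3, n - ACA_TAIL)
    lo, hi = 0, n
    if structure is not None:
        pins = [p for p in _hairpins(structure)]
        if len(pins) >= 2:
            # hinge between the two 3'-most hairpins
            lo, hi = pins[-2][1], pins[-1][0]
    h = None
    m = len(h_consensus)
    for i in range(lo, hi - m + 1):
        if match_consensus(seq[i:i + m], h_consensus):
            h = (i, i + m)
            break
    return h, aca


def find_cab_box(seq: str, structure: PairTable,
                 consensus: str = CAB_BOX_CONSENSUS) -> Optional[tuple[int, int]]:
    """CAB box in the distal loop of the 3'-most hairpin (optional motif)."""
    seq = normalize_rna(seq)
    pins = _hairpins(structure)
    if not pins:
        return None
    lo, hi = pins[-1]
    m = len(consensus)
    for i in range(lo, hi - m + 1):
        if match_consensus(seq[i:i + m], consensus):
            return (i, i + m)
    return None


def assign_ends(genomic_seq: str, hit_start: int, hit_end: int,
                promoter_window: int = 50,
                tata_offset: int = TATA_TSS_OFFSET,
                ) -> tuple[int, str, Optional[int]]:
    """Predict transcript ends around a genomic hit.

    5' end: ``tata_offset`` nt downstream of the nearest upstream TATA motif
    within ``promoter_window`` of the hit start; falls back to the hit start
    (origin ``"given"``) when no TATA is found.  3' end: the last ACA within
    the hit tail plus ``ACA_TAIL`` nt; None when no ACA is present.
    Returns ``(five_prime, origin, three_prime)`` in genomic coordinates.
    """
    g = genomic_seq.upper().replace("U", "T")
    lo = max(0, hit_start - promoter_window)
    tata = g.rfind("TATA", lo, hit_start)
    if tata >= 0:
        five = tata + tata_offset
        origin = "TATA_proximity"
    else:
        five = hit_start
        origin = "given"
    # last ACA in the neighbourhood of the hit 3' end
    tail_lo = max(0, hit_end - 15)
    tail_hi = min(len(g), hit_end + 6)
    aca = g.rfind("ACA", tail_lo, tail_hi)
    three = aca + 3 + ACA_TAIL if aca >= 0 else None
    return five, origin, three


_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def element_presence(seq: str, structure: PairTable,
                     min_canonical_frac: float = 0.7) -> dict[str, bool]:
    """Presence flag per named helix: enough of its pairs close canonically."""
    seq = normalize_rna(seq)
    flags: dict[str, bool] = {}
    by_name: dict[str, list[tuple[int, int]]] = {}
    for (i, j), name in structure.element_names.items():
        by_name.setdefault(name, []).append((i, j))
    for name, pairs in by_name.items():
        ok = sum((seq[i], seq[j]) in _CANONICAL for i, j in pairs
                 if j < len(seq))
        flags[name] = bool(pairs) and ok / len(pairs) >= min_canonical_frac
    # CR4/5 vs eCR4/5 heuristic: a CR4/5-region stem without a P6.1-like
    # terminal stem-loop is flagged as the structurally reduced eCR4/5
    if "P6" in flags:
        flags["CR4/5"] = flags["P6"] and flags.get("P6.1", False)
        flags["eCR4/5"] = flags["P6"] and not flags.get("P6.1", False)
    return flags


def annotate(seq: str, repeat_unit: str,
             structure: Optional[PairTable] = None,
             max_mismatches: int = 0,
             detect_cab: bool = False) -> TRAnnotation:
    """Full annotation of a candidate TR sequence."""
    seq = normalize_rna(seq)
    ann = TRAnnotation(repeat_unit=repeat_unit)
    span = find_template(seq, repeat_unit, max_mismatches=max_mismatches)
    if span is not None:
        ann.template_span = span
        ann.template_seq = seq[span[0]:span[1]]
    if structure is not None and span is not None:
        ann.tbe_type, ann.tbe_anchor = classify_tbe(seq, structure, span)
    if len(seq) >= 10:
        ann.h_box, ann.aca_box = find_haca_boxes(seq, structure)
    if ann.aca_box is not None:
        ann.three_prime_end = ann.aca_box[1] + ACA_TAIL
    if structure is not None:
        ann.elements = element_presence(seq, structure)
        ann.elements["H/ACA"] = ann.h_box is not None and ann.aca_box is not None
        if detect_cab:
            cab = find_cab_box(seq, structure)
            ann.cab_box = cab
            ann.elements["CAB"] = cab is not None
    ann.validate()
    return ann


def annotation_to_gff3(ann: TRAnnotation, seq_id: str) -> str:
    """Render an annotation as GFF3 lines (1-based inclusive coordinates)."""
    rows = []

    def add(ftype: str, span: Optional[tuple[int, int]], attrs: str = "") -> None:
        if span is None:
            return
        rows.append("\t".join([
            seq_id, "trscout", ftype, str(span[0] + 1), str(span[1]),
            ".", "+", ".", attrs or f"ID={ftype}"]))

    add("template", ann.template_span)
    add("TBE", ann.tbe_anchor, f"ID=TBE;tbe_type={ann.tbe_type}")
    add("H_box", ann.h_box)
    add("ACA_box", ann.aca_box)
    add("CAB_box", ann.cab_box)
    return "##gff-version 3\n" + "\n".join(rows) + ("\n" if rows else "")
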