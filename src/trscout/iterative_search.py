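"""Phylogeny-guided reiterative homology search.

Drives the outward march across clades: scan the phylogenetically nearest
target genome with the current profile, verify candidate hits for TR
hallmarks (template, box H/ACA, realised consensus pairing), absorb each
accepted hit into the alignment by projecting it onto profile columns via
its alignment trace, rebuild the profile, and proceed to the next clade.
Hits absorbed from nearer species broaden the profile so that more distant
homologs, invisible to the seed profile, become detectable in later rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

from .msa_io import StructuredAlignment, normalize_rna
from .profile_model import DEFAULT_PSEUDOCOUNT, TRProfile, build_profile
from .structure_scan import Hit, ScanConfig, scan
from .tr_annotate import find_haca_boxes, find_template, match_consensus, \
    H_BOX_CONSENSUS


@dataclass(frozen=True)
class PlanTarget:
    clade_name: str
    records: list[tuple[str, str]]
    rank: int
    config_overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhylogenyPlan:
    """Targets ordered by phylogenetic distance from the seed clade."""

    targets: tuple[PlanTarget, ...]

    def __post_init__(self) -> None:
        ranks = [t.rank for t in self.targets]
        if sorted(ranks) != ranks or len(set(ranks)) != len(ranks):
            raise ValueError("plan ranks must be strictly increasing")
        names = [t.clade_name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValueError("clade names must be unique")


@dataclass(frozen=True)
class VerifyConfig:
    """Checklist applied to every candidate before absorption."""

    repeat_unit: str = "TTAGGG"
    check_template: bool = True
    check_haca: bool = True
    min_pair_frac: float = 0.7
    #: the assigned ACA+3 3' end must land within this many nt of the
    #: candidate region boundary
    tail_slack: int = 6
    h_consensus: str = H_BOX_CONSENSUS
    template_mismatches: int = 0
    max_accept_per_target: int = 1


@dataclass
class SearchRound:
    index: int
    clade: str
    considered: list[Hit]
    accepted: list[tuple[Hit, str]]      # (hit, new row id)
    rejections: list[tuple[Hit, list[str]]]
    profile_before: str
    profile_after: str

    def to_json(self) -> str:
        return json.dumps({
            "round": self.index,
            "clade": self.clade,
            "n_considered": len(self.considered),
            "accepted": [rid for _, rid in self.accepted],
            "rejections": [{"target": h.target_id, "start": h.start,
                            "reasons": rs} for h, rs in self.rejections],
            "profile_before": self.profile_before,
            "profile_after": self.profile_after,
        })


def verify_hit(hit: Hit, profile: TRProfile,
               config: VerifyConfig) -> tuple[bool, list[str]]:
    """Structural-plausibility checklist; returns (accept, failed checks)."""
    reasons: list[str] = []
    seq = normalize_rna(hit.region_seq)
    if config.check_template:
        span = find_template(seq, config.repeat_unit,
                             max_mismatches=config.template_mismatches)
        if span is None:
            reasons.append("template")
    if config.check_haca:
        aca_ok = False
        pos = seq.rfind("ACA")
        while pos >= 0:
            assigned = pos + 3 + 3  # ACA end + 3 nt tail
            if abs(assigned - len(seq)) <= config.tail_slack:
                aca_ok = True
                break
            pos = seq.rfind("ACA", 0, pos)
        if not aca_ok:
            reasons.append("ACA_box")
        m = len(config.h_consensus)
        half = len(seq) // 2
        h_ok = any(match_consensus(seq[i:i + m], config.h_consensus)
                   for i in range(half, len(seq) - m + 1))
        if not h_ok:
            reasons.append("H_box")
    realized = realized_pair_fraction(hit, profile)
    if realized < config.min_pair_frac:
        reasons.append("pair_support")
    return (not reasons), reasons


_CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def realized_pair_fraction(hit: Hit, profile: TRProfile) -> float:
    """Fraction of consensus nested pairs closed canonically in the hit."""
    seq = normalize_rna(hit.region_seq)
    matched = {c: w for op, c, w in hit.trace if op == "M"}
    pairs = profile.pairs.nested
    if not pairs:
        return 1.0
    good = 0
    for i, j in pairs:
        wi, wj = matched.get(i), matched.get(j)
        if wi is not None and wj is not None and (seq[wi], seq[wj]) in _CANON:
            good += 1
    return good / len(pairs)


def hit_to_aligned_row(hit: Hit, profile: TRProfile) -> tuple[str, int]:
    """Project a hit onto profile columns via its trace.

    Insertions relative to the profile are dropped from the row (the
    profile length never changes); their count is returned as metadata.
    """
    seq = normalize_rna(hit.region_seq)
    row = ["-"] * profile.length
    n_insertions = 0
    for op, c, w in hit.trace:
        if op == "M":
            row[c] = seq[w]
        elif op == "I":
            n_insertions += 1
    return "".join(row), n_insertions


def _profile_id(profile: TRProfile) -> str:
    import hashlib
    return hashlib.sha1(profile.to_json().encode()).hexdigest()[:12]


def run_iterative(seed_aln: StructuredAlignment,
                  plan: PhylogenyPlan,
                  scan_config: ScanConfig,
                  verify_config: VerifyConfig,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  feature_cols: Optional[dict[str, tuple[int, int]]] = None,
                  ) -> tuple[StructuredAlignment, list[SearchRound]]:
    """Run the reiterative search over the plan's clades in rank order.

    Accepted hits are appended as alignment rows (trace projection, no
    realignment) and the profile is rebuilt before the next clade.
    Verification failures are recorded in the round audit, never fatal.
    """
    aln = seed_aln
    rounds: list[SearchRound] = []
    for idx, target in enumerate(sorted(plan.targets, key=lambda t: t.rank)):
        profile = build_profile(aln, pseudocount=pseudocount,
                                feature_cols=feature_cols)
        pid_before = _profile_id(profile)
        cfg = replace(scan_config, **target.config_overrides) \
            if target.config_overrides else scan_config
        hits = scan(profile, target.records, cfg)
        accepted: list[tuple[Hit, str]] = []
        rejections: list[tuple[Hit, list[str]]] = []
        for hit in hits:  # already sorted by score descending
            if len(accepted) >= verify_config.max_accept_per_target:
                break
            ok, reasons = verify_hit(hit, profile, verify_config)
            if not ok:
                rejections.append((hit, reasons))
                continue
            row, _n_ins = hit_to_aligned_row(hit, profile)
            row_id = (f"{target.clade_name}|{hit.target_id}|"
                      f"{hit.start + 1}-{hit.end}({hit.strand})")
            aln = aln.with_row(row_id, row)
            accepted.append((hit, row_id))
        profile_after = build_profile(aln, pseudocount=pseudocount,
                                      feature_cols=feature_cols)
        rounds.append(SearchRound(
            index=idx, clade=target.clade_name, considered=hits,
            accepted=accepted, rejections=rejections,
            profile_before=pid_before,
            profile_after=_profile_id(profile_after)))
    return aln, rounds


def rounds_to_jsonl(rounds: list[SearchRound]) -> str:
    return "\n".join(r.to_json() for r in rounds) + ("\n" if rounds else "")
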