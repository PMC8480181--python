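"""Shared fixture for the phylogeny-guided reiterative-search tests.

An outward-march family: three seed taxa close to the ancestor, a near
clade of four genomes (~0.25 substitutions/site), a mid clade of four
genomes one further hop out, and a distant homolog one more hop beyond.
The hop sizes and the 89-bit acceptance threshold were calibrated so the
distant homolog is undetectable to the seed profile alone but detectable
after the two nearer clades have been absorbed.
"""

from trscout.iterative_search import PhylogenyPlan, PlanTarget, VerifyConfig
from trscout.msa_io import StructuredAlignment
from trscout.structure_scan import ScanConfig
from trscout.synthetic_data import FamilySpec, SyntheticFamily, plant, \
    sample_family

MARCH_TREE = ("((S1:0.5,S2:0.5,S3:0.5):0.01,"
              "(X1:0.2,X2:0.2,X3:0.2,X4:0.2,"
              "(Y1:0.2,Y2:0.2,Y3:0.2,Y4:0.2,F:2.5):2.5):2.5);")
THRESHOLD = 89.0
GENOME_LENGTH = 1000
NEAR = ["X1", "X2", "X3", "X4"]
MID = ["Y1", "Y2", "Y3", "Y4"]
DISTANT = "F"


def make_march_fixture(seed: int):
    """Family + seed alignment + per-clade genomes + distant truth row."""
    spec = FamilySpec(tree=MARCH_TREE, subst_rate=0.1,
                      compensatory_prob=0.98, indel_rate=0.0, seed=seed)
    family = sample_family(spec)
    seed_aln = StructuredAlignment(
        rows=[(n, family.leaves[n].aligned) for n in ("S1", "S2", "S3")],
        consensus_structure=spec.structure)

    def genome(leaf, off):
        sub = SyntheticFamily(spec=spec, ancestor=family.ancestor,
                              leaves={leaf: family.leaves[leaf]})
        return plant(sub, GENOME_LENGTH, seed=seed * 31 + off)

    near_records, mid_records = [], []
    for off, leaf in enumerate(NEAR):
        g, _ = genome(leaf, off + 1)
        near_records += g
    for off, leaf in enumerate(MID):
        g, _ = genome(leaf, off + 5)
        mid_records += g
    far_records, far_truth = genome(DISTANT, 9)
    plan = PhylogenyPlan((PlanTarget("near", near_records, 0),
                          PlanTarget("mid", mid_records, 1),
                          PlanTarget("far", far_records, 2)))
    scan_cfg = ScanConfig(score_threshold=THRESHOLD, seed=0, max_candidates=1)
    verify_cfg = VerifyConfig(repeat_unit=spec.repeat_unit,
                              max_accept_per_target=4)
    return spec, family, seed_aln, plan, scan_cfg, verify_cfg, \
        far_records, far_truth.iloc[0]


def overlaps_truth(hits, truth_row) -> bool:
    return any(h.target_id == truth_row.genome_id
               and h.start < truth_row.end and truth_row.start < h.end
               for h in hits)
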