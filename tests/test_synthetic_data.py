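import numpy as np
import pytest
from scipy import stats

from trscout.msa_io import brackets_to_pairtable
from trscout.synthetic_data import (DEFAULT_MARKOV, FamilySpec, SpecError,
                                    divergence, plant, sample_family)
from trscout.tr_annotate import annotate

CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class TestFamilySpec:
    def test_template_copies_bounds(self):
        with pytest.raises(SpecError, match="template_copies"):
            FamilySpec(template_copies=2.5)

    def test_custom_structure_missing_features_listed(self):
        with pytest.raises(SpecError) as err:
            FamilySpec(structure="((((....))))",
                       feature_cols={"template": (2, 13)})
        msg = str(err.value)
        assert "pseudoknot" in msg and "H box" in msg

    def test_default_structure_has_pseudoknot_and_named_helices(self):
        spec = FamilySpec()
        pt = spec.pair_table()
        assert pt.pseudoknot
        assert {"P1.1", "P2b", "P3", "P6", "P6.1", "P7a", "P8"} <= \
            set(pt.element_names.values())


class TestSampleFamily:
    def test_zero_rate_leaves_identical_to_ancestor(self):
        spec = FamilySpec(subst_rate=0.0, indel_rate=0.0, seed=4)
        fam = sample_family(spec)
        for leaf in fam.leaves.values():
            assert leaf.seq == fam.ancestor

    def test_full_compensation_keeps_every_pair_canonical(self):
        spec = FamilySpec(subst_rate=0.3, compensatory_prob=1.0,
                          indel_rate=0.0, seed=9)
        fam = sample_family(spec)
        for leaf in fam.leaves.values():
            for i, j in leaf.pair_table.nested:
                pair = (leaf.seq[i], leaf.seq[j])
                assert pair in CANON, (i, j, pair)

    def test_same_seed_reproduces_family(self):
        a = sample_family(FamilySpec(seed=21))
        b = sample_family(FamilySpec(seed=21))
        assert a.ancestor == b.ancestor
        assert {n: l.seq for n, l in a.leaves.items()} == \
            {n: l.seq for n, l in b.leaves.items()}

    def test_ancestor_satisfies_all_constraints(self):
        spec = FamilySpec(seed=3)
        anc = sample_family(spec).ancestor
        t = spec.feature_cols["template"]
        assert anc[t[0]:t[1]] == "CCUAACCCUAA"
        a = spec.feature_cols["ACA_box"]
        assert anc[a[0]:a[1]] == "ACA" and len(anc) - a[1] == 3
        for i, j in brackets_to_pairtable(spec.structure).nested:
            assert (anc[i], anc[j]) in CANON

    def test_ground_truth_rederivable_by_annotator(self):
        """The generator/annotator loop closes on every leaf."""
        spec = FamilySpec(seed=17, subst_rate=0.15, indel_rate=0.02)
        fam = sample_family(spec)
        for leaf in fam.leaves.values():
            ann = annotate(leaf.seq, spec.repeat_unit,
                           structure=leaf.pair_table)
            assert ann.template_span == leaf.annotation.template_span
            assert ann.aca_box == leaf.annotation.aca_box
            assert ann.three_prime_end == len(leaf.seq)

    def test_realized_divergence_matches_rate(self):
        """Mean realized divergence over a 100-seed sweep sits within 3
        standard errors of the per-edge substitution probability."""
        p = 0.12
        spec0 = FamilySpec(seed=0, tree="(A:1,B:1);", subst_rate=p,
                           compensatory_prob=0.5, indel_rate=0.0)
        frozen = _frozen_count(spec0)
        n_free = spec0.length - frozen
        divs = []
        for seed in range(100):
            spec = FamilySpec(seed=seed, tree="(A:1,B:1);", subst_rate=p,
                              compensatory_prob=0.5, indel_rate=0.0)
            fam = sample_family(spec)
            anc, leaf = fam.ancestor, fam.leaves["A"]
            pairs = [(x, y) for c, (x, y) in enumerate(zip(anc, leaf.seq))
                     if c in _free_columns(spec)]
            divs.append(sum(x != y for x, y in pairs) / len(pairs))
        mean = np.mean(divs)
        # per-pair correlation inflates the variance by at most 2x
        se = np.sqrt(2 * p * (1 - p) / n_free) / np.sqrt(len(divs))
        assert abs(mean - p) <= 3 * se


def _free_columns(spec):
    from trscout.synthetic_data import _frozen_columns
    return set(range(spec.length)) - _frozen_columns(spec)


def _frozen_count(spec):
    from trscout.synthetic_data import _frozen_columns
    return len(_frozen_columns(spec))


class TestPlant:
    def test_roundtrip_extraction(self, small_family):
        spec, fam = small_family
        genomes, truth = plant(fam, 2000, seed=3)
        by_id = dict(genomes)
        for _, row in truth.iterrows():
            insert = by_id[row.genome_id][row.start:row.end]
            leaf_dna = fam.leaves[row.leaf].seq.replace("U", "T")
            assert insert == leaf_dna

    def test_reverse_strand_plantings(self, small_family):
        from trscout.msa_io import revcomp_dna
        spec, fam = small_family
        strands = {name: "-" for name in fam.leaves}
        genomes, truth = plant(fam, 2000, strands=strands, seed=5)
        by_id = dict(genomes)
        for _, row in truth.iterrows():
            insert = by_id[row.genome_id][row.start:row.end]
            assert revcomp_dna(insert) == \
                fam.leaves[row.leaf].seq.replace("U", "T")

    def test_markov_background_reproduces_dinucleotide_bias(self, small_family):
        """Chi-square test of observed vs expected dinucleotide counts on a
        100 kb Markov background."""
        from trscout.synthetic_data import _background
        rng = np.random.default_rng(0)
        g = _background(100_000, "markov1", rng)
        P = DEFAULT_MARKOV / DEFAULT_MARKOV.sum(axis=1, keepdims=True)
        # stationary distribution of the chain
        vals, vecs = np.linalg.eig(P.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = pi / pi.sum()
        idx = {b: k for k, b in enumerate("ACGT")}
        counts = np.zeros((4, 4))
        for a, b in zip(g, g[1:]):
            counts[idx[a], idx[b]] += 1
        expected = pi[:, None] * P * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p_value = 1 - stats.chi2.cdf(chi2, df=15)
        assert p_value > 1e-3

    def test_overflow_rejected(self, small_family):
        spec, fam = small_family
        name = next(iter(fam.leaves))
        with pytest.raises(ValueError, match="overflow"):
            plant(fam, 2000, positions={name: 1990}, seed=0)

    def test_zero_plantings_unreachable_background_only(self):
        spec = FamilySpec(seed=2)
        fam = sample_family(spec)
        fam.leaves = {}
        genomes, truth = plant(fam, 500, seed=1)
        assert genomes == [] and truth.empty
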