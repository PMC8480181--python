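import numpy as np
import pytest

from trscout.msa_io import PairTable, StructuredAlignment
from trscout.profile_model import TRProfile
from trscout.synthetic_data import FamilySpec, sample_family


@pytest.fixture
def toy_alignment() -> StructuredAlignment:
    """Four rows over a hairpin plus one pseudoknot pair layer."""
    return StructuredAlignment(
        rows=[
            ("sp1", "GGACAUCC"),
            ("sp2", "GGACAUCC"),
            ("sp3", "CGACAUCG"),
            ("sp4", "CGAC-UCG"),
        ],
        consensus_structure="((....))",
    )


@pytest.fixture
def random_profile_factory():
    """Profiles with random PWMs and a chosen nested pair set."""

    def make(length: int, pairs, seed: int = 0,
             pk_pairs=(), gap_free: bool = True) -> TRProfile:
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(4) * 1.2, size=length)
        all_pairs = frozenset(
            {(i, j, "nested") for i, j in pairs}
            | {(i, j, "pseudoknot") for i, j in pk_pairs})
        return TRProfile(
            length=length,
            col_freqs=freqs,
            gap_freq=np.zeros(length),
            pairs=PairTable(all_pairs),
            background=np.full(4, 0.25),
            pseudocount=0.5,
        )

    return make


@pytest.fixture
def small_family():
    """Low-divergence four-leaf family (shared across slow-ish tests)."""
    spec = FamilySpec(seed=11, subst_rate=0.05, compensatory_prob=0.95,
                      indel_rate=0.005)
    return spec, sample_family(spec)
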