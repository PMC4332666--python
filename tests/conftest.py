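import numpy as np
import pytest

from kindredx import (
    SampleCallSet,
    SimulationConfig,
    VariantCall,
    simulate_cohort,
    simulate_reference_panel,
)


def make_call(pos, ref="A", alt="G", chrom="X", genotype=1.0, depth=30,
              alt_fwd=15, alt_rev=15, func_class="other"):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
                       depth=depth, alt_fwd=alt_fwd, alt_rev=alt_rev, func_class=func_class)


def make_callset(sample_id, positions, **kwargs):
    return SampleCallSet(sample_id, [make_call(p, **kwargs) for p in positions])


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down cohort: 6 sporadic + 4 pairs, ~250 variants/sample."""
    return SimulationConfig(
        n_sporadic=6,
        n_brother_pairs=3,
        n_half_brother_pairs=1,
        n_cousin_pairs=0,
        n_uncle_nephew_pairs=0,
        n_panel_variants=2_500,
        n_private_per_haplotype=12,
        batch_size=6,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    panel = simulate_reference_panel(small_cfg, 11)
    cohort = simulate_cohort(small_cfg, panel, 12)
    return panel, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)
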