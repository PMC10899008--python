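import numpy as np
import pytest

from regmk.genome_io import Stratum
from regmk.synthetic_data import SimParams, simulate_sequences


@pytest.fixture(scope="session")
def small_bundle():
    """A small fixed cohort shared by read-only tests."""
    params = SimParams(seed=11, chrom_length=120_000, n_acrs=24, n_genes=24, n_repeats=12)
    return simulate_sequences(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flat_params(**overrides) -> SimParams:
    """SimParams with a single stratum and uniform rates, for calibration
    scenarios where ACRs and controls must be exchangeable."""
    from regmk.genome_io import GenomicInterval

    defaults = dict(
        seed=0,
        n_genes=0,
        n_repeats=0,
        acr_rate_multiplier_y=1.0,
        acr_rate_multiplier_x=1.0,
        d_x={Stratum.S1: 0.02},
        d_y={Stratum.S1: 0.02},
        theta_x=0.0,
        theta_auto=0.0,
        auto_length=1_000,
    )
    defaults.update(overrides)
    params = SimParams(**defaults)
    params.strata_bounds = [
        GenomicInterval("chrXY", 0, params.chrom_length, stratum=Stratum.S1)
    ]
    return params
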