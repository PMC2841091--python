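import numpy as np
import pytest

from resarray import PipelineConfig, analyze_batch, tile_probes
from resarray.pipeline import simulate_default_batch
from resarray.simulate import random_reference


@pytest.fixture(scope="session")
def default_batch():
    """The default calibrated study batch: 24 arrays x 26,292 positions.

    Shared across tests because it is the (seeded) condition under which
    the headline claims — no-call rate, rescue fraction, accuracy — are
    evaluated.
    """
    cfg = PipelineConfig(n_arrays=24).with_seed(1)
    design, truths, samples = simulate_default_batch(cfg)
    result = analyze_batch(
        design,
        samples,
        call_params=cfg.caller,
        q=cfg.sprofiler.q,
        alpha=cfg.sprofiler.alpha,
        mode=cfg.sprofiler.mode,
        min_run=cfg.sprofiler.min_run,
        filter_params=cfg.filters,
        truths=truths,
    )
    return cfg, result


@pytest.fixture(scope="session")
def small_design():
    """A 3-fragment, 150-position design on a seeded random reference."""
    ref = random_reference(400, gc=0.45, seed=11)
    regions = [(20, 70, "exA"), (120, 170, "exB"), (220, 270, "exC")]
    return tile_probes(ref, regions, probe_length=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
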