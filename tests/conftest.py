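import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import nucbarrier as nb
from nucbarrier.coverage import ProcessingParams

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zero_jitter_cfg() -> nb.SimConfig:
    """Fully deterministic nucleosome positions: every cell identical."""
    return nb.SimConfig(
        seed=5, p_bound=1.0, n_cells=50,
        sigma_plus_one=0.0, sigma_minus_one=0.0, sigma_step=0.0,
        sigma_plus_one_free=0.0, sigma_step_free=0.0, frag_sd=0.0,
    )


@pytest.fixture(scope="session")
def zero_jitter_run(zero_jitter_cfg) -> nb.ConditionRun:
    """50-gene, 1e5-read pipeline run with zero positional noise."""
    return nb.run_condition(zero_jitter_cfg)


@pytest.fixture(scope="session")
def wt_run() -> nb.ConditionRun:
    """Study-condition run with the TF barrier bound in every cell."""
    cfg = nb.SimConfig(seed=20, p_bound=1.0)
    return nb.run_condition(cfg, params=ProcessingParams(flank=800))


@pytest.fixture(scope="session")
def mut_run(wt_run) -> nb.ConditionRun:
    """The matched barrier-free (TF-deletion-like) run."""
    return nb.run_condition(wt_run.cfg.barrier_free(), params=ProcessingParams(flank=800))


@pytest.fixture
def small_cfg() -> nb.SimConfig:
    """A fast configuration for unit tests."""
    return nb.SimConfig(seed=3, n_genes=4, n_cells=100, total_reads=20_000)
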