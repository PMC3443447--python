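import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wingarray import RunConfig, run_pipeline, scaled_config
from wingarray.datagen import generate_design, simulate_intensities

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A 600-contig simulated dataset with default noise and planted effects."""
    cfg = scaled_config(seed=11, n_contigs=600)
    design = generate_design(cfg)
    table, probemap, truth = simulate_intensities(design, cfg)
    return cfg, design, table, probemap, truth


@pytest.fixture(scope="session")
def recovery_run():
    """The scaled-down recovery run: 2,000 contigs, default noise, seed 1."""
    cfg = RunConfig(generator=scaled_config(seed=1), seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """1,000 contigs with no planted tissue effects (null calibration)."""
    cfg = scaled_config(
        seed=17, n_contigs=1000,
        effect_fractions={"null": 0.5, "stage_only": 0.5},
    )
    design = generate_design(cfg)
    table, probemap, truth = simulate_intensities(design, cfg)
    return cfg, design, table, probemap, truth


def summarize_raw_log2(table: pd.DataFrame) -> pd.DataFrame:
    """Contig-level plain log2 expression (no normalization), for oracles."""
    import numpy as np

    from wingarray.preprocess import META_COLUMNS, sample_columns, summarize_probes

    log2d = table.copy()
    cols = sample_columns(table)
    log2d[cols] = np.log2(table[cols])
    return summarize_probes(log2d)
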