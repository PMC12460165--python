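import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import statscore as ss
from statscore import pipeline, simdata

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SMALL_PROGRAMS = {s: 40 for s in simdata.STATS}


def make_count_matrix(counts: dict[str, list[int]], conditions: dict[str, tuple[str, str | None]],
                      sample_condition: dict[str, str]) -> ss.CountMatrix:
    """Small hand-built CountMatrix; conditions maps name -> (role, reference_stat)."""
    counts_df = pd.DataFrame(counts)
    counts_df.index = [f"g{i}" for i in range(len(counts_df))]
    samples = pd.DataFrame(
        {
            "condition": [sample_condition[s] for s in counts_df.columns],
            "role": [conditions[sample_condition[s]][0] for s in counts_df.columns],
            "reference_stat": [conditions[sample_condition[s]][1] for s in counts_df.columns],
        },
        index=pd.Index(counts_df.columns, name="sample"),
    )
    return ss.CountMatrix(counts_df, samples)


@pytest.fixture(scope="session")
def default_sim():
    """The full-size default simulation: 2,000 genes, control + 6 references, n=3."""
    return simdata.simulate_experiment(simdata.SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A light simulation (500 genes) for structural checks."""
    cfg = simdata.SimConfig(n_genes=500, program_sizes=SMALL_PROGRAMS, seed=11)
    return cfg, simdata.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def fixture_config_path():
    from pathlib import Path

    return Path(__file__).resolve().parents[1] / "fixtures" / "default_run.yaml"


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, fixture_config_path):
    """One completed pipeline run on the packaged fixture config."""
    out = tmp_path_factory.mktemp("run") / "default"
    cfg = pipeline.load_config(fixture_config_path)
    cfg.out_dir = out
    manifest = pipeline.run_pipeline(cfg)
    return out, manifest
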