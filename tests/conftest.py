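import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from endoqtl import cyclestage, expression, synthdata

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """A 229-sample cohort with 400 variants / 400 probes and known truth."""
    cfg = synthdata.SimConfig(n_samples=229, n_variants=400, seed=1)
    g = synthdata.simulate_genotypes(cfg)
    samples = synthdata.simulate_samples(cfg)
    truth, probes = synthdata.make_truth(g, 400, seed=2)
    ds = synthdata.simulate_expression(g, samples, truth, probes, seed=3)
    return dict(cfg=cfg, g=g, samples=samples, truth=truth, probes=probes, ds=ds)


@pytest.fixture(scope="session")
def tracks(cohort):
    """Detection calls, partition, normalised matrix and merged-stage samples."""
    ds = cohort["ds"]
    calls = expression.call_detection(ds)
    part = expression.partition_probes(calls)
    norm = expression.quantile_normalize_log2(ds)
    samples = expression.attach_quality(cohort["samples"], calls)
    merged = cyclestage.combine_stages(samples)
    return dict(calls=calls, part=part, norm=norm, samples=samples, merged=merged)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def study_stage_table() -> pd.DataFrame:
    """Sample table expanded from the published histological stage counts."""
    rows = []
    i = 0
    for stage, n in synthdata.STUDY_STAGE_COUNTS.items():
        for _ in range(n):
            rows.append((f"W{i:03d}", stage, "control"))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "stage", "disease"])
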