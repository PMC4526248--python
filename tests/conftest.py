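import time

import pytest

import gaitsync as gs


@pytest.fixture(scope="session")
def cohort_true():
    """Default 16-runner cohort, true step times only (no accelerometer synthesis)."""
    dataset = gs.simulate_cohort(gs.CohortConfig(seed=1), synth_traces=False)
    metrics = gs.compute_metrics(dataset, use_detected=False)
    return dataset, metrics


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete default pipeline run (simulate -> detect -> score -> analyze)."""
    outdir = tmp_path_factory.mktemp("full_run")
    config = gs.validate_config({"seed": 1})
    t0 = time.perf_counter()
    manifest = gs.run_experiment(config, outdir)
    elapsed = time.perf_counter() - t0
    return {"outdir": outdir, "manifest": manifest, "elapsed_s": elapsed, "config": config}
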