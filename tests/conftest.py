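"""Shared fixtures: a seeded 500-trace cohort scanned once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from editscan.cluster_scan import ScanConfig, scan_trace
from editscan.placement import PlacementOutcome, place_traces
from editscan.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default 500-trace cohort with planted editing and artifact signals."""
    cfg = SimConfig(seed=COHORT_SEED, n_traces=500)
    reference, repeats, traces, truth, alt_calls = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "reference": reference,
        "repeats": repeats,
        "traces": traces,
        "truth": truth,
        "alt_calls": alt_calls,
    }


@pytest.fixture(scope="session")
def cohort_scan(cohort):
    """Placements and per-trace runs (min_run=3, any quality) for the cohort."""
    reference = cohort["reference"]
    traces = cohort["traces"]
    by_id = {t.trace_id: t for t in traces}
    placements = place_traces(traces, reference)
    scfg = ScanConfig(min_run=3, min_span_bp=0)
    runs_by_trace = {}
    for tid, pl in placements.items():
        if pl.outcome is not PlacementOutcome.UNIQUE:
            continue
        runs = scan_trace(pl.record, reference, by_id[tid], scfg)
        if runs:
            runs_by_trace[tid] = runs
    return {"placements": placements, "runs_by_trace": runs_by_trace}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
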