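import pytest

from clipsplice.io import pool_tracks
from clipsplice.simulate import SimConfig, simulate_all
from clipsplice.splicing import (
    call_intron_retention,
    detect_junction_events,
    differential_splicing,
)


@pytest.fixture(scope="session")
def sim_study():
    """Study-scale synthetic dataset: 150 genes, depth 200, all event types."""
    return simulate_all(SimConfig(seed=5, n_genes=150, frac_as=0.6))


@pytest.fixture(scope="session")
def sim_study_analysis(sim_study):
    """Detection + IR calling + differential table for the study dataset."""
    data = sim_study
    det = detect_junction_events(data.models, data.junctions)
    cond_cov = {
        cond: pool_tracks([data.coverage[s] for s in names])
        for cond, names in data.samples.items()
    }
    ir = {}
    for cond, cov in sorted(cond_cov.items()):
        for ev in call_intron_retention(data.models, cov):
            ir[ev.event_id] = ev
    ir_events = [ir[k] for k in sorted(ir)]
    events = det.events + ir_events
    rase = differential_splicing(
        events, data.junctions, data.samples, coverage=cond_cov
    )
    return dict(
        detection=det, ir_events=ir_events, events=events, rase=rase,
        cond_cov=cond_cov,
    )


@pytest.fixture(scope="session")
def sim_tiny():
    return simulate_all(SimConfig(seed=1, n_genes=24))
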