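"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pytest

import fbpm


@pytest.fixture(scope="session")
def spec28():
    """2.8 μm diameter bead (Dynabeads M-270 class: density 1.6 g/cm³)."""
    return fbpm.ParticleSpec(radius_um=1.4, density_p=1.6)


@pytest.fixture(scope="session")
def spec1():
    """1 μm diameter bead (MyOne class: density 1.8 g/cm³)."""
    return fbpm.ParticleSpec(radius_um=0.5, density_p=1.8)


@pytest.fixture(scope="session")
def sandwich_run(spec28):
    """One 300 s sandwich-assay recording at the half-saturation
    concentration: 30 particles of 2.8 μm with ground truth, plus the
    diffusivity traces and segmented states at the published 0.05 μm²/s
    cutoff."""
    scen = fbpm.KineticScenario()
    cfg = fbpm.SimConfig(n_particles=30, seed=42)
    trajset, gt = fbpm.simulate_fov(spec28, scen, cfg, concentration=scen.c_half)
    traces = [fbpm.diffusivity_trace(t) for t in trajset]
    seg = fbpm.SegmentationConfig.for_cutoff(0.05)
    states = [
        fbpm.segment_states(tr, seg, full_frames=t.frame, full_times=t.t_s)
        for t, tr in zip(trajset, traces)
    ]
    return {
        "scenario": scen,
        "config": cfg,
        "trajset": trajset,
        "gt": gt,
        "traces": traces,
        "states": states,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
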