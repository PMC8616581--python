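"""Shared fixtures: scripted tracks and moderately sized simulations."""

from __future__ import annotations

import numpy as np
import pytest

from larvanet import simulate as sim
from larvanet.core import Track, TrackSet
from larvanet.simulate import _render_spines


def make_track(
    larva_id: str = "L0",
    duration: float = 10.0,
    frame_rate: float = 14.0,
    heading=0.0,
    speed: float = 1.0,
    body_length: float = 4.0,
    bend=None,
    start=(0.0, 0.0),
) -> Track:
    """Build a kinematically scripted track.

    ``heading`` (radians) and ``bend`` (radians, anterior bend) may be
    scalars or per-frame arrays; the centroid integrates ``speed`` along the
    heading.
    """
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    head = np.broadcast_to(np.asarray(heading, dtype=float), (n,)).copy()
    b = np.zeros(n) if bend is None else np.broadcast_to(np.asarray(bend, dtype=float), (n,)).copy()
    pos = np.zeros((n, 2))
    pos[0] = start
    step = speed / frame_rate
    for i in range(1, n):
        pos[i] = pos[i - 1] + step * np.array([np.cos(head[i - 1]), np.sin(head[i - 1])])
    spine = _render_spines(pos, head, b, body_length)
    return Track(larva_id=larva_id, t=t, spine=spine, centroid=pos, body_length=body_length)


@pytest.fixture(scope="session")
def stimulus_med():
    return sim.simulate_stimulus(300.0, seed=101)


@pytest.fixture(scope="session")
def lnp_med(stimulus_med):
    """Medium LNP simulation shared across revcorr tests."""
    tracks, truth = sim.simulate_larvae_lnp(stimulus_med, n_larvae=25, seed=202)
    return stimulus_med, tracks, truth


@pytest.fixture(scope="session")
def lnp_sharp():
    """LNP simulation with a fast kernel and strong sweep-acceptance link."""
    stim = sim.simulate_stimulus(500.0, seed=303)
    kern = sim.default_true_kernel(tau=0.15)
    tracks, truth = sim.simulate_larvae_lnp(
        stim, kernel=kern, n_larvae=30, seed=304, accept_slope=4.0
    )
    return stim, tracks, truth


@pytest.fixture(scope="session")
def connectome_clean():
    return sim.simulate_connectome(fp_rate=0.0, seed=404)


@pytest.fixture(scope="session")
def calcium_default():
    return sim.simulate_calcium(n_individuals=10, n_trials=4, seed=505)
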