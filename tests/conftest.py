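"""Shared fixtures: small synthetic scenes and a reference DLA cluster.

Everything is generated at test time from fixed seeds; the heavy objects
are session-scoped so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from camulm.config import SceneConfig
from camulm.dla import generate_dla_cluster
from camulm.scene import generate_vessel_network, simulate_mb_trajectories, synthesize_iq

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dla_cluster_20k() -> np.ndarray:
    """20,000-particle lattice DLA cluster, fixed seed."""
    return generate_dla_cluster(20000, seed=1)


@pytest.fixture(scope="session")
def rank3_scene():
    """Standard clutter-filter scene: exact rank-3 tissue, 10 bubbles,
    no noise, 600 frames of a 1.5 × 2.0 mm field."""
    cfg = SceneConfig(field_depth_mm=1.5, field_width_mm=2.0, n_frames=600,
                      n_bubbles=10, branching_depth=2, clutter_rank=3,
                      clutter_to_mb_db=30.0, noise_sigma=0.0, seed=5)
    net = generate_vessel_network(cfg)
    traj = simulate_mb_trajectories(net, cfg)
    return cfg, synthesize_iq(traj, net, cfg)


@pytest.fixture(scope="session")
def tumor_regime_scene():
    """Scene matched to the in vivo clutter regime: rank-15 tissue 30 dB
    above the bubbles plus depth-law noise, 800 frames."""
    cfg = SceneConfig(field_depth_mm=1.5, field_width_mm=2.0, n_frames=800,
                      n_bubbles=20, branching_depth=2, noise_sigma=0.02, seed=3)
    net = generate_vessel_network(cfg)
    traj = simulate_mb_trajectories(net, cfg)
    return cfg, synthesize_iq(traj, net, cfg)


@pytest.fixture()
def circle_control_points():
    """8 control points on a unit circle centered at (1.5, 1.5) mm."""
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    return np.column_stack([1.5 + np.cos(ang), 1.5 + np.sin(ang)])
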