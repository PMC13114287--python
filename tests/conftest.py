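"""Shared fixtures: simulated colonies and reduced model-search settings.

Simulated datasets are session-scoped because several test modules probe
different properties of the same generating mechanism; problem sizes are
chosen so the whole suite runs on one CPU in minutes while keeping enough
transition events (hundreds per dataset) for stable AUC estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import anthazard as ah

warnings.filterwarnings("ignore", message=".*single-class labels.*")


#: reduced hyperparameter search used throughout the tests (full default
#: grids only change runtime, not the behaviour under test)
FAST = dict(l1_ratios=(0.5,), strengths=(1e-3, 1e-2, 1e-1, 1.0), inner_folds=2)


def fast_spec(**kw) -> ah.ModelSpec:
    merged = {**FAST, **kw}
    return ah.ModelSpec(**merged)


def brute_force_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """All-pairs AUC estimator: P(score_case > score_control), ties 1/2."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def _prepare(preset_name: str, n_ants: int, n_frames: int, seed: int, with_phi=False):
    cfg = ah.preset(preset_name, n_ants=n_ants, n_frames=n_frames, seed=seed)
    traj, truth = ah.simulate_colony(cfg)
    states, bouts, events = ah.segment(traj)
    phi = None
    if with_phi:
        dense = ah.pivot_dense(states, traj)
        phi = ah.run_field(dense.x, dense.y, cfg.pheromone, cfg.frame_rate)
    designs = {}
    for tt in ("stop", "start"):
        d = ah.assemble_design(states, traj, tt, phi=phi)
        designs[tt] = {
            "full": d,
            "sampled": ah.incidence_density_sample(d, ratio=10, seed=seed),
        }
    return {
        "config": cfg,
        "traj": traj,
        "truth": truth,
        "states": states,
        "bouts": bouts,
        "events": events,
        "designs": designs,
    }


@pytest.fixture(scope="session")
def memoryless_data():
    """Constant-hazard colony (stop 0.01, start 0.02 per frame)."""
    return _prepare("memoryless", n_ants=20, n_frames=8000, seed=11)


@pytest.fixture(scope="session")
def inertia_data():
    """Duration-dependent hazards only (negative dwell coefficient)."""
    return _prepare("inertia", n_ants=30, n_frames=6000, seed=7)


@pytest.fixture(scope="session")
def imitation_data():
    """Social hazards only (fraction of resting neighbours)."""
    return _prepare("imitation", n_ants=40, n_frames=6000, seed=4)


@pytest.fixture(scope="session")
def full_data():
    """All three mechanisms active, with the reconstructed pheromone field."""
    return _prepare("full", n_ants=40, n_frames=6000, seed=5, with_phi=True)
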