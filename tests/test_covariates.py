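"""Neighbourhood features, lag handling and design-matrix contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import anthazard as ah
from anthazard.covariates import (
    FeatureConfig,
    fraction_resting,
    heading_dispersion,
    local_density,
    neighbour_indices,
    speed_difference,
)


class TestSingleFrameFeatures:
    def test_local_density_formula(self):
        # 3 neighbours inside R = 1.5 -> 3 / (pi 1.5^2) ~ 0.4244
        pos = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [5, 5]])
        assert local_density(pos, 0, 1.5) == pytest.approx(3 / (np.pi * 1.5**2))
        assert local_density(np.array([[0.0, 0.0]]), 0, 1.5) == 0.0

    def test_neighbour_ball_is_closed(self):
        pos = np.array([[0.0, 0.0], [1.5, 0.0]])
        assert list(neighbour_indices(pos, 0, 1.5)) == [1]

    def test_fraction_resting_and_isolated_fill(self):
        states = np.array([1, 0, 0, 1, 1])
        assert fraction_resting(states, np.array([1, 2, 3, 4])) == (0.5, 0)
        assert fraction_resting(states, np.array([], dtype=int)) == (0.5, 1)
        assert fraction_resting(states, np.array([1, 2]))[0] == 1.0

    def test_speed_difference(self):
        speeds = np.array([2.0, 1.0, 3.0, 5.0])
        assert speed_difference(speeds, 0, np.array([1, 2])) == pytest.approx(0.0)
        assert speed_difference(speeds, 0, np.array([], dtype=int)) == 0.0
        assert speed_difference(np.array([5.0, 0, 0, 0]), 0, np.array([1, 2, 3])) == 5.0

    def test_heading_dispersion_closed_forms(self):
        # identical differences -> Rbar = 1 -> s = 0
        h = np.array([0.5, 0.5, 0.5])
        assert heading_dispersion(h, 0, np.array([1, 2])) == pytest.approx(0.0)
        # +-60 degrees -> Rbar = cos 60 = 0.5 -> s = sqrt(-2 ln 0.5)
        h = np.array([0.0, np.pi / 3, -np.pi / 3])
        assert heading_dispersion(h, 0, np.array([1, 2])) == pytest.approx(
            np.sqrt(-2 * np.log(0.5)), abs=1e-12
        )
        # uniform on 4 quadrants -> Rbar = 0 -> capped
        h = np.array([0.0, 0.0, np.pi / 2, np.pi, -np.pi / 2])
        assert heading_dispersion(h, 0, np.array([1, 2, 3, 4]), cap=4.0) == 4.0
        # undefined focal heading -> neutral fill cap/2
        h = np.array([np.nan, 0.0])
        assert heading_dispersion(h, 0, np.array([1]), cap=4.0) == 2.0


class TestVectorisedAgainstBruteForce:
    @given(
        n=st.integers(2, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dense_features_match_per_frame_scan(self, n, seed):
        """The chunked vectorised features equal the direct per-ant scan."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(-4, 4, (1, n))
        y = rng.uniform(-4, 4, (1, n))
        state = rng.integers(0, 2, (1, n)).astype(float)
        speed = rng.uniform(0, 3, (1, n))
        cfg = FeatureConfig(radius=1.5, lag=0)
        feats = ah.compute_feature_arrays(x, y, state, speed, cfg)
        pos = np.column_stack([x[0], y[0]])
        for i in range(n):
            nbr = neighbour_indices(pos, i, cfg.radius)
            assert feats["local_density"][0, i] == pytest.approx(
                local_density(pos, i, cfg.radius)
            )
            fr, iso = fraction_resting(state[0], nbr)
            assert feats["fraction_resting"][0, i] == pytest.approx(fr)
            assert feats["isolated_flag"][0, i] == iso
            assert feats["speed_difference"][0, i] == pytest.approx(
                speed_difference(speed[0], i, nbr)
            )

    def test_density_brute_force_scan_200_ants(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-10, 10, (200, 2))
        cfg = FeatureConfig(radius=1.5)
        feats = ah.compute_feature_arrays(
            pos[None, :, 0], pos[None, :, 1],
            np.zeros((1, 200)), np.zeros((1, 200)), cfg,
        )
        expected = np.array([local_density(pos, i, 1.5) for i in range(200)])
        np.testing.assert_allclose(feats["local_density"][0], expected)


def _resting_colony(n_frames=40, n_ants=4):
    rows = []
    for a in range(n_ants):
        for t in range(n_frames):
            rows.append((a, t, 10.0 * a, 0.0))
    return pd.DataFrame(rows, columns=["ant_id", "frame", "x", "y"])


class TestAssembleDesign:
    def test_lag_excludes_early_bout_frames(self):
        traj = _resting_colony()
        states = ah.classify_states(ah.compute_speeds(traj))
        design = ah.assemble_design(states, traj, "start", cfg=FeatureConfig(lag=3))
        # bout entry is at frame 1 (frame 0 has undefined speed); with k = 3
        # the first at-risk frame is 4 and log_dwell there is log(0 + 1) = 0
        assert design["frame"].min() == 4
        assert design["log_dwell"].min() == 0.0

    def test_lag_zero_reads_transition_frame(self):
        traj = _resting_colony()
        states = ah.classify_states(ah.compute_speeds(traj))
        design = ah.assemble_design(states, traj, "start", cfg=FeatureConfig(lag=0))
        assert design["frame"].min() == 1

    def test_label_rate_matches_generating_hazard(self, memoryless_data):
        """On ground-truth states the fraction of labelled at-risk rows
        equals the generating per-frame hazard."""
        truth = memoryless_data["truth"].assign(speed=np.nan)
        traj = memoryless_data["traj"]
        for tt, p in (("start", 0.02), ("stop", 0.01)):
            d = ah.assemble_design(truth, traj, tt)
            assert d["y"].mean() == pytest.approx(p, rel=0.1)

    def test_covariate_ranges(self, imitation_data):
        for tt in ("stop", "start"):
            d = imitation_data["designs"][tt]["full"]
            assert d["fraction_resting"].between(0, 1).all()
            assert d["heading_dispersion"].between(0, 4.0).all()
            assert (d["log_dwell"] >= 0).all()
            assert np.isfinite(d.drop(columns=["colony", "transition_type"]).to_numpy(float)).all()

    def test_unlagged_dwell_option(self):
        traj = _resting_colony()
        states = ah.classify_states(ah.compute_speeds(traj))
        cfg = FeatureConfig(lag=3, lag_dwell=False)
        design = ah.assemble_design(states, traj, "start", cfg=cfg)
        assert design["log_dwell"].min() == pytest.approx(np.log(3 + 1))

    def test_no_leakage_from_future_frames(self, inertia_data):
        """Perturbing every frame after t - k leaves the covariates of row
        (ant, t) unchanged: no covariate reads the future."""
        states = inertia_data["states"]
        traj = inertia_data["traj"]
        cfg = FeatureConfig(lag=3)
        design = ah.assemble_design(states, traj, "stop", cfg=cfg)
        row = design.iloc[len(design) // 2]
        t_cut = int(row["frame"]) - cfg.lag
        traj2 = traj.copy()
        future = traj2["frame"] > t_cut
        rng = np.random.default_rng(0)
        traj2.loc[future, ["x", "y"]] += rng.uniform(50, 500, (future.sum(), 2))
        design2 = ah.assemble_design(states, traj2, "stop", cfg=cfg)
        key_cols = ["ant_id", "frame"]
        cov_cols = ["local_density", "fraction_resting", "speed_difference",
                    "heading_dispersion", "isolated_flag", "log_dwell"]
        merged = design.merge(design2, on=key_cols, suffixes=("", "_p"))
        at_t = merged[merged["frame"] == int(row["frame"])]
        assert len(at_t) > 0
        for c in cov_cols:
            np.testing.assert_allclose(at_t[c], at_t[c + "_p"], atol=1e-12)

    def test_mismatched_indices_rejected(self):
        traj = _resting_colony()
        states = ah.classify_states(ah.compute_speeds(traj))
        with pytest.raises(ValueError, match="mismatched"):
            ah.assemble_design(states, traj[traj["frame"] < 20], "start")
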