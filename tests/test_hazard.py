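"""Sampling, grouped CV, AUC, model comparison, transfer, hazard curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

import anthazard as ah
from anthazard.segmentation import MOVING, RESTING
from conftest import brute_force_auc, fast_spec


def _toy_design(n_frames=30, ants=6, events_per_frame=1, seed=0):
    """Small synthetic design: one case per chosen frame, rest controls."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_frames):
        cases = rng.choice(ants, size=events_per_frame, replace=False)
        for a in range(ants):
            rows.append((a, t, int(a in cases), rng.normal()))
    return pd.DataFrame(rows, columns=["ant_id", "frame", "y", "log_dwell"])


class TestIncidenceDensitySampling:
    def test_exactly_ratio_controls_when_eligible(self):
        # one case and 25 eligible controls per frame, ratio 10
        d = _toy_design(n_frames=20, ants=26)
        s = ah.incidence_density_sample(d, ratio=10, seed=0)
        per_frame = s.groupby("frame").agg(cases=("y", "sum"), rows=("y", "size"))
        assert (per_frame["cases"] == 1).all()
        assert (per_frame["rows"] == 11).all()
        assert s.attrs["control_shortfall"] == 0

    def test_shortfall_takes_all_eligible(self):
        d = _toy_design(n_frames=5, ants=5)  # only 4 eligible controls
        s = ah.incidence_density_sample(d, ratio=10, seed=0)
        assert (s.groupby("frame").size() == 5).all()
        assert s.attrs["control_shortfall"] == 5 * 6

    def test_deterministic_under_seed(self):
        d = _toy_design(n_frames=50, ants=30)
        s1 = ah.incidence_density_sample(d, ratio=10, seed=9)
        s2 = ah.incidence_density_sample(d, ratio=10, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_cases_rejected(self):
        d = _toy_design().assign(y=0)
        with pytest.raises(ValueError, match="no transition events"):
            ah.incidence_density_sample(d)


class TestAUC:
    def test_worked_example(self):
        # cases score 0.9, 0.8; controls 0.7, 0.85 -> 3 of 4 pairs won
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.85])
        assert brute_force_auc(y, s) == 0.75
        assert roc_auc_score(y, s) == 0.75

    @given(
        n=st.integers(10, 60),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ranking_auc_equals_all_pairs_estimator(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, int)
        y[: n // 3 + 1] = 1
        scores = rng.integers(0, 5, n) if ties else rng.normal(size=n)
        assert roc_auc_score(y, scores) == pytest.approx(
            brute_force_auc(y, scores.astype(float))
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        assert roc_auc_score(y, s) == pytest.approx(roc_auc_score(y, np.exp(2 * s)))


class TestGroupFolds:
    def test_each_ant_in_exactly_one_fold(self):
        folds = ah.make_group_folds(np.arange(10), n_folds=5, seed=1)
        assert sorted(folds) == list(range(10))
        sizes = pd.Series(folds).value_counts()
        assert (sizes == 2).all()

    def test_fewer_ants_than_folds_rejected(self):
        with pytest.raises(ValueError, match="distinct ants"):
            ah.make_group_folds([1, 2, 3], n_folds=5)


class TestPenalisedHazardModel:
    def test_sklearn_protocol(self):
        m = ah.PenalisedHazardModel(l1_ratios=(0.5,), strengths=(0.01, 0.1))
        assert clone(m).get_params()["inner_folds"] == m.inner_folds
        m.set_params(seed=3)
        assert m.seed == 3

    def test_perfect_separation_reaches_auc_one(self):
        d = _toy_design(n_frames=40, ants=12, seed=1)
        d["log_dwell"] = d["y"] * 10.0 + np.random.default_rng(0).normal(0, 0.1, len(d))
        res = ah.grouped_cv(d, fast_spec(features=("dwell",), cv_folds=3))
        assert res.auc_mean > 0.99

    def test_uninformative_covariates_near_chance(self):
        d = _toy_design(n_frames=120, ants=40, seed=2)  # noise covariate
        res = ah.grouped_cv(d, fast_spec(features=("dwell",)))
        assert res.auc_mean == pytest.approx(0.5, abs=0.05)

    def test_probabilities_valid(self):
        d = _toy_design(n_frames=40, ants=12)
        X = d[["log_dwell"]].to_numpy()
        m = ah.PenalisedHazardModel(l1_ratios=(0.5,), strengths=(0.1,)).fit(
            X, d["y"].to_numpy()
        )
        p = m.predict_proba(X)[:, 1]
        assert ((p > 0) & (p < 1)).all()


class TestFitOrchestration:
    def test_grouped_cv_scores_every_row_out_of_fold(self, inertia_data):
        s = inertia_data["designs"]["stop"]["sampled"]
        res = ah.grouped_cv(s, fast_spec(features=("dwell",)))
        assert res.oof_score.notna().all()
        assert len(res.fold_aucs) == 5
        # each ant's rows are scored by the model of exactly one fold
        fold = s["ant_id"].map(res.fold_of_ant)
        assert fold.nunique() == 5

    def test_fit_hazard_reports_coefficients(self, inertia_data):
        s = inertia_data["designs"]["stop"]["sampled"]
        res = ah.fit_hazard(s, fast_spec(features=("dwell",)))
        # behavioural inertia: longer dwell -> lower stop hazard
        assert res.coefficients["log_dwell"] < 0

    def test_sampling_ratio_does_not_bias_auc(self, inertia_data):
        """AUC at 10:1 vs 50:1 case-control ratios agree within 0.01."""
        full = inertia_data["designs"]["start"]["full"]
        spec = fast_spec(features=("dwell",), transition_type="start")
        aucs = []
        for ratio in (10, 50):
            s = ah.incidence_density_sample(full, ratio=ratio, seed=1)
            aucs.append(ah.grouped_cv(s, spec).auc_mean)
        assert abs(aucs[0] - aucs[1]) < 0.01

    def test_noise_covariate_changes_paired_auc_little(self, inertia_data):
        """Adding a pure-noise covariate on identical rows and folds moves
        the mean AUC by < 0.01."""
        s = inertia_data["designs"]["stop"]["sampled"].copy()
        rng = np.random.default_rng(0)
        s["noise"] = rng.normal(size=len(s))
        spec = fast_spec(features=("dwell",))
        table, _ = ah.compare_models(
            s, spec, {"dwell": ("dwell",), "dwell+noise": ("dwell", "noise")}
        )
        a = table.set_index("variant")["auc_mean"]
        assert abs(a["dwell"] - a["dwell+noise"]) < 0.01


class TestCrossColony:
    def test_identical_colonies_have_near_zero_gap(self, inertia_data):
        s = inertia_data["designs"]["stop"]["sampled"]
        designs = {"A": s, "B": s.copy()}
        res = ah.cross_colony(designs, fast_spec(features=("dwell",)))
        assert res.matrix.shape == (2, 2)
        assert abs(res.gap) < 0.02

    def test_three_colony_matrix_shape(self):
        designs = {}
        for i, name in enumerate("ABC"):
            cfg = ah.preset("inertia", n_ants=12, n_frames=1200, seed=20 + i)
            traj, _ = ah.simulate_colony(cfg)
            states, _, _ = ah.segment(traj)
            d = ah.assemble_design(states, traj, "start", colony=name)
            designs[name] = ah.incidence_density_sample(d, 10, seed=i)
        res = ah.cross_colony(designs, fast_spec(features=("dwell",), cv_folds=3))
        m = res.matrix
        assert m.shape == (3, 3) and m.notna().all().all()
        assert res.within_mean == pytest.approx(np.diag(m.to_numpy()).mean())

    def test_single_colony_rejected(self, inertia_data):
        with pytest.raises(ValueError, match="at least 2"):
            ah.cross_colony(
                {"A": inertia_data["designs"]["stop"]["sampled"]},
                fast_spec(features=("dwell",)),
            )


class TestEmpiricalHazardCurve:
    def test_constant_hazard_bouts(self):
        """Geometric bouts -> every filled bin estimates the constant rate."""
        rng = np.random.default_rng(0)
        durations = rng.geometric(0.05, 3000)
        rows, events, frame = [], [], 0
        for i, L in enumerate(durations):
            rows.append((0, MOVING, frame, frame + L))
            events.append((0, frame + L - 1, "stop"))
            frame += L
        bouts = pd.DataFrame(rows, columns=["ant_id", "state", "start_frame", "end_frame"])
        bouts["duration"] = bouts["end_frame"] - bouts["start_frame"]
        ev = pd.DataFrame(events, columns=["ant_id", "frame", "type"])
        curve = ah.empirical_hazard_curve(
            bouts, ev, state=MOVING, bin_edges_s=np.array([0, 1, 2, 4, 8])
        )
        for _, row in curve[curve["n_risk"] > 500].iterrows():
            assert row["hazard"] == pytest.approx(0.05, abs=3 * row["se"])

    def test_deterministic_duration_spike(self):
        # all bouts exactly 10 frames: hazard 0 below dwell 9, 1 at dwell 9
        bouts = pd.DataFrame(
            {
                "ant_id": 0,
                "state": MOVING,
                "start_frame": np.arange(0, 200, 10),
                "end_frame": np.arange(10, 210, 10),
                "duration": 10,
            }
        )
        ev = pd.DataFrame(
            {"ant_id": 0, "frame": np.arange(9, 209, 10), "type": "stop"}
        )
        curve = ah.empirical_hazard_curve(
            bouts, ev, state=MOVING, frame_rate=10.0,
            bin_edges_s=np.array([0.0, 0.9, 1.0, 2.0]),
        )
        assert curve["hazard"].iloc[0] == 0.0
        assert curve["hazard"].iloc[1] == 1.0
        assert bool(curve["empty"].iloc[2])

    def test_censored_bouts_contribute_no_final_trial(self):
        # a single censored bout: no events anywhere, hazard 0 in filled bins
        bouts = pd.DataFrame(
            {"ant_id": [0], "state": [RESTING], "start_frame": [0],
             "end_frame": [50], "duration": [50]}
        )
        ev = pd.DataFrame(columns=["ant_id", "frame", "type"])
        curve = ah.empirical_hazard_curve(
            bouts, ev, state=RESTING, bin_edges_s=np.array([0, 2, 4, 8])
        )
        assert curve["n_risk"].sum() == 49
        assert (curve["n_events"] == 0).all()
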