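"""Elastic-net logistic hazard models with ant-grouped cross-validation.

The discrete-time hazard of leaving the current behavioural state is
modelled as ``lambda = sigmoid(beta0 + beta^T X)`` and fitted as a penalised
logistic regression on incidence-density-sampled at-risk rows.  Evaluation
is by out-of-fold AUC under cross-validation grouped by ant identity, so a
model is always scored on ants it never saw; the elastic-net mixing
parameter and strength are tuned by an inner grouped CV within each
training fold.

:class:`PenalisedHazardModel` is a scikit-learn estimator (clone- and
pipeline-compatible); the surrounding functions orchestrate sampling,
fold bookkeeping, model comparison on paired folds, cross-colony transfer
and empirical hazard curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y

from .covariates import NEIGHBOUR_COLUMNS
from .pheromone import residualise_phi
from .segmentation import MOVING

logger = logging.getLogger("anthazard")

__all__ = [
    "ModelSpec",
    "FitResult",
    "CrossColonyResult",
    "PenalisedHazardModel",
    "incidence_density_sample",
    "grouped_cv",
    "fit_hazard",
    "compare_models",
    "cross_colony",
    "empirical_hazard_curve",
    "DEFAULT_VARIANTS",
]

#: named covariate subsets compared throughout; keys mirror the candidate
#: mechanisms (social neighbourhood, internal state via dwell, stigmergy)
DEFAULT_VARIANTS: dict[str, tuple[str, ...]] = {
    "phi_only": ("phi",),
    "neighbours_only": ("neighbours",),
    "dwell_only": ("dwell",),
    "neighbours_phi": ("neighbours", "phi"),
    "dwell_phi": ("dwell", "phi"),
    "neighbours_dwell": ("neighbours", "dwell"),
    "full": ("neighbours", "dwell", "phi"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one hazard-model fit."""

    transition_type: str = "stop"
    features: tuple[str, ...] = ("neighbours", "dwell")
    ratio: int = 10
    cv_folds: int = 5
    inner_folds: int = 3
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    strengths: tuple[float, ...] = tuple(np.logspace(-4, 1, 10))
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature_set must be non-empty")
        if self.cv_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be at least 2")
        if self.ratio < 1:
            raise ValueError("case:control ratio must be at least 1")


def feature_columns(features: tuple[str, ...]) -> list[str]:
    """Covariate family names -> design-matrix columns."""
    cols: list[str] = []
    for f in features:
        if f == "neighbours":
            cols.extend(NEIGHBOUR_COLUMNS)
        elif f == "dwell":
            cols.append("log_dwell")
        elif f == "phi":
            cols.append("phi_resid")
        else:
            cols.append(f)  # raw column name, e.g. a test-only noise covariate
    return cols


def make_group_folds(groups, n_folds: int, seed: int = 0) -> dict:
    """Deterministic balanced fold assignment per group (ant).

    Groups are shuffled under the seed and dealt round-robin, giving fold
    sizes differing by at most one ant.
    """
    uniq = np.sort(np.unique(np.asarray(groups)))
    if len(uniq) < n_folds:
        raise ValueError(f"need at least {n_folds} distinct ants, got {len(uniq)}")
    order = np.random.default_rng(seed).permutation(len(uniq))
    return {uniq[g]: i % n_folds for i, g in enumerate(order)}


class PenalisedHazardModel(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic hazard with internal grouped hyperparameter search.

    Features are standardised with training statistics inside the model.
    When more than one (l1_ratio, strength) combination is supplied, the
    pair maximising mean inner grouped-CV AUC is chosen and the model is
    refitted on all training rows.  ``strength`` is the penalty weight on
    the standardised scale (sklearn ``C = 1/strength``).

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : ndarray
        Coefficients on the standardised feature scale.
    l1_ratio_, strength_ : float
        Chosen hyperparameters.
    """

    def __init__(
        self,
        l1_ratios=(0.1, 0.5, 0.9),
        strengths=tuple(np.logspace(-4, 1, 10)),
        inner_folds: int = 3,
        seed: int = 0,
        max_iter: int = 300,
        tol: float = 1e-3,
    ):
        self.l1_ratios = l1_ratios
        self.strengths = strengths
        self.inner_folds = inner_folds
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def _pipeline(self, l1_ratio: float, strength: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logistic",
                    LogisticRegression(
                        solver="saga",
                        l1_ratio=l1_ratio,
                        C=1.0 / strength,
                        max_iter=self.max_iter,
                        tol=self.tol,
                        random_state=self.seed,
                    ),
                ),
            ]
        )

    def fit(self, X, y, groups=None):
        X, y = check_X_y(X, y)
        grid = [(l1, s) for l1 in self.l1_ratios for s in self.strengths]
        if len(grid) > 1:
            if groups is None:
                groups = np.arange(len(y))
            fold_of = make_group_folds(groups, self.inner_folds, self.seed)
            fold = np.array([fold_of[g] for g in np.asarray(groups)])
            scores = []
            for l1, s in grid:
                aucs = []
                for f in range(self.inner_folds):
                    tr, te = fold != f, fold == f
                    if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                        warnings.warn(f"inner fold {f} has single-class labels; skipped")
                        continue
                    pipe = self._pipeline(l1, s).fit(X[tr], y[tr])
                    aucs.append(roc_auc_score(y[te], pipe.predict_proba(X[te])[:, 1]))
                scores.append(np.mean(aucs) if aucs else -np.inf)
            best = int(np.argmax(scores))
            self.inner_scores_ = np.asarray(scores)
        else:
            best = 0
            self.inner_scores_ = None
        self.l1_ratio_, self.strength_ = grid[best]
        self.pipeline_ = self._pipeline(self.l1_ratio_, self.strength_).fit(X, y)
        lr = self.pipeline_.named_steps["logistic"]
        self.coef_ = lr.coef_[0]
        self.intercept_ = lr.intercept_[0]
        self.classes_ = lr.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(X)

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(X)


def incidence_density_sample(design: pd.DataFrame, ratio: int = 10, seed: int = 0) -> pd.DataFrame:
    """Case-control sampling of the at-risk design matrix.

    Every case row (y = 1) is retained; for each frame containing ``c``
    cases, ``c * ratio`` control rows are drawn uniformly without
    replacement from that frame's non-transitioning same-state rows.  When
    fewer controls are eligible all are taken and the shortfall is logged.
    Deterministic under the seed.
    """
    if design["y"].sum() == 0:
        raise ValueError("design contains no transition events; nothing to sample")
    rng = np.random.default_rng(seed)
    y = design["y"].to_numpy()
    frames = design["frame"].to_numpy()
    case_frames, case_counts = np.unique(frames[y == 1], return_counts=True)
    frame_groups = {f: idx for f, idx in design.groupby("frame").indices.items()}
    keep = [np.where(y == 1)[0]]
    shortfall = 0
    for f, c in zip(case_frames, case_counts):
        rows = frame_groups[f]
        elig = rows[y[rows] == 0]
        want = int(c) * ratio
        if len(elig) <= want:
            shortfall += want - len(elig)
            keep.append(elig)
        else:
            keep.append(rng.choice(elig, size=want, replace=False))
    if shortfall:
        logger.info("incidence-density sampling shortfall: %d controls", shortfall)
    idx = np.sort(np.concatenate(keep))
    out = design.iloc[idx].reset_index(drop=True)
    out.attrs["control_shortfall"] = int(shortfall)
    return out


@dataclass
class FitResult:
    """Grouped-CV result for one covariate subset."""

    transition_type: str
    features: tuple[str, ...]
    fold_aucs: np.ndarray
    auc_mean: float
    auc_se: float
    oof_score: pd.Series
    fold_of_ant: dict
    fold_hyperparams: list[tuple[float, float]]
    coefficients: pd.Series | None = None
    fold_models: list = field(default_factory=list, repr=False)

    @property
    def oof_deviance(self) -> float:
        """Total out-of-fold binomial deviance (scored rows only)."""
        scores = self.oof_score.to_numpy()
        mask = np.isfinite(scores)
        p = np.clip(scores[mask], 1e-12, 1 - 1e-12)
        y = np.asarray(self._y)[mask]
        return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _design_matrix(design: pd.DataFrame, features: tuple[str, ...], train_mask=None) -> np.ndarray:
    """Extract (and residualise, if needed) the covariate block."""
    df = design
    if "phi" in features:
        if "phi" not in design.columns:
            raise ValueError("feature set includes phi but design has no phi column")
        df = design.copy()
        df["phi_resid"] = residualise_phi(
            design["phi"].to_numpy(), design["local_density"].to_numpy(), train_mask
        )
    return df[feature_columns(features)].to_numpy(dtype=float)


def grouped_cv(design: pd.DataFrame, spec: ModelSpec, fold_of_ant: dict | None = None) -> FitResult:
    """Ant-grouped outer cross-validation of one covariate subset.

    Every row's out-of-fold score comes from a model that never saw that
    ant; per-fold AUCs are summarised as mean +/- sd/sqrt(folds).  The
    pheromone covariate is residualised against local density using
    training-fold rows only.
    """
    if fold_of_ant is None:
        fold_of_ant = make_group_folds(design["ant_id"], spec.cv_folds, spec.seed)
    fold = design["ant_id"].map(fold_of_ant).to_numpy()
    y = design["y"].to_numpy()
    oof = np.full(len(design), np.nan)
    fold_aucs, hypers, models = [], [], []
    for f in range(spec.cv_folds):
        tr, te = fold != f, fold == f
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn(f"outer fold {f} has single-class labels; skipped")
            hypers.append(None)
            continue
        X = _design_matrix(design, spec.features, train_mask=tr)
        model = PenalisedHazardModel(
            l1_ratios=spec.l1_ratios,
            strengths=spec.strengths,
            inner_folds=spec.inner_folds,
            seed=spec.seed + f,
            max_iter=spec.max_iter,
        )
        model.fit(X[tr], y[tr], groups=design["ant_id"].to_numpy()[tr])
        p = model.predict_proba(X[te])[:, 1]
        oof[te] = p
        fold_aucs.append(roc_auc_score(y[te], p))
        hypers.append((model.l1_ratio_, model.strength_))
        models.append(model)
    fold_aucs = np.asarray(fold_aucs)
    result = FitResult(
        transition_type=spec.transition_type,
        features=spec.features,
        fold_aucs=fold_aucs,
        auc_mean=float(fold_aucs.mean()),
        auc_se=float(fold_aucs.std(ddof=1) / np.sqrt(len(fold_aucs))) if len(fold_aucs) > 1 else 0.0,
        oof_score=pd.Series(oof, index=design.index),
        fold_of_ant=fold_of_ant,
        fold_hyperparams=hypers,
        fold_models=models,
    )
    result._y = y
    return result


def fit_hazard(design: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Grouped CV plus a final refit on all rows for reportable coefficients."""
    result = grouped_cv(design, spec)
    X = _design_matrix(design, spec.features)
    final = PenalisedHazardModel(
        l1_ratios=spec.l1_ratios,
        strengths=spec.strengths,
        inner_folds=spec.inner_folds,
        seed=spec.seed,
        max_iter=spec.max_iter,
    ).fit(X, design["y"].to_numpy(), groups=design["ant_id"].to_numpy())
    result.coefficients = pd.Series(final.coef_, index=feature_columns(spec.features))
    result.fold_models.append(final)
    return result


def _oof_deviance(design: pd.DataFrame, features: tuple[str, ...], spec: ModelSpec) -> float:
    """Out-of-fold binomial deviance of one covariate subset."""
    from dataclasses import replace

    return grouped_cv(design, replace(spec, features=tuple(features))).oof_deviance


def compare_models(
    design: pd.DataFrame,
    spec: ModelSpec,
    variants: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit every covariate-subset variant on identical rows and folds.

    The same sampled design and the same ant-to-fold assignment are reused
    across variants so AUC differences are paired comparisons.

    Returns the comparison table (variant, transition_type, auc_mean,
    auc_se) and the per-variant :class:`FitResult` objects.
    """
    if variants is None:
        variants = {
            k: v
            for k, v in DEFAULT_VARIANTS.items()
            if "phi" not in v or "phi" in design.columns
        }
    fold_of_ant = make_group_folds(design["ant_id"], spec.cv_folds, spec.seed)
    from dataclasses import replace

    rows, results = [], {}
    for name, feats in variants.items():
        res = grouped_cv(design, replace(spec, features=tuple(feats)), fold_of_ant=fold_of_ant)
        results[name] = res
        rows.append(
            {
                "variant": name,
                "transition_type": spec.transition_type,
                "auc_mean": res.auc_mean,
                "auc_se": res.auc_se,
            }
        )
    return pd.DataFrame(rows), results


@dataclass
class CrossColonyResult:
    """Train-colony x test-colony AUC matrix for one covariate subset."""

    matrix: pd.DataFrame
    within_mean: float
    cross_mean: float

    @property
    def gap(self) -> float:
        return self.within_mean - self.cross_mean


def cross_colony(designs: dict[str, pd.DataFrame], spec: ModelSpec) -> CrossColonyResult:
    """Cross-colony transfer of one covariate subset.

    Diagonal entries are within-colony grouped-CV mean AUCs; off-diagonal
    entries come from a model fitted on the entire training colony
    (hyperparameters by inner grouped CV) and evaluated on the entire
    sampled design of the test colony.
    """
    if len(designs) < 2:
        raise ValueError("cross-colony transfer needs at least 2 colonies")
    for name, d in designs.items():
        if d is None or len(d) == 0:
            raise ValueError(f"missing design for colony {name!r}")
    colonies = list(designs)
    mat = pd.DataFrame(np.nan, index=colonies, columns=colonies, dtype=float)
    for train in colonies:
        d_tr = designs[train]
        mat.loc[train, train] = grouped_cv(d_tr, spec).auc_mean
        X_tr = _design_matrix(d_tr, spec.features)
        model = PenalisedHazardModel(
            l1_ratios=spec.l1_ratios,
            strengths=spec.strengths,
            inner_folds=spec.inner_folds,
            seed=spec.seed,
            max_iter=spec.max_iter,
        ).fit(X_tr, d_tr["y"].to_numpy(), groups=d_tr["ant_id"].to_numpy())
        for test in colonies:
            if test == train:
                continue
            d_te = designs[test]
            if "phi" in spec.features:
                # residualisation coefficients come from the training colony
                df = d_te.copy()
                beta = np.polynomial.polynomial.polyfit(
                    d_tr["local_density"], d_tr["phi"], 1
                )
                df["phi_resid"] = d_te["phi"] - (beta[0] + beta[1] * d_te["local_density"])
                X_te = df[feature_columns(spec.features)].to_numpy(float)
            else:
                X_te = _design_matrix(d_te, spec.features)
            p = model.predict_proba(X_te)[:, 1]
            mat.loc[train, test] = roc_auc_score(d_te["y"], p)
    diag = np.diag(mat.to_numpy())
    off = mat.to_numpy()[~np.eye(len(colonies), dtype=bool)]
    return CrossColonyResult(
        matrix=mat, within_mean=float(diag.mean()), cross_mean=float(off.mean())
    )


def default_hazard_bins(frame_rate: float = 10.0) -> np.ndarray:
    """Dwell-time bin edges (seconds): 0.1 s up to 2 s, then log-spaced to 60 s."""
    fine = np.arange(0.0, 2.0 + 1e-9, 0.1)
    coarse = np.geomspace(2.0, 60.0, 13)[1:]
    return np.concatenate([fine, coarse])


def empirical_hazard_curve(
    bouts: pd.DataFrame,
    events: pd.DataFrame,
    state: int = MOVING,
    frame_rate: float = 10.0,
    bin_edges_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical discrete hazard as a function of dwell time.

    For each dwell bin, hazard = (bouts ending with dwell in the bin) /
    (bout-frames at risk in the bin).  A bout of duration ``L`` that ends in
    an observed transition contributes at-risk frames at dwell 0..L-1 and an
    event at dwell L-1; a censored bout (gap or end of recording) contributes
    at-risk frames 0..L-2 only, since its final transition trial is
    unobserved.  The per-bin standard error is binomial.
    """
    if bin_edges_s is None:
        bin_edges_s = default_hazard_bins(frame_rate)
    edges = np.asarray(bin_edges_s, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    b = bouts[bouts["state"] == state]
    ev_frames = set(zip(events["ant_id"], events["frame"]))
    n_risk = np.zeros(len(edges) - 1)
    n_event = np.zeros(len(edges) - 1)
    edges_frames = edges * frame_rate
    for _, row in b.iterrows():
        L = int(row["duration"])
        has_event = (row["ant_id"], row["end_frame"] - 1) in ev_frames
        d_max = L if has_event else L - 1  # at-risk dwells are 0..d_max-1
        if d_max <= 0:
            continue
        counts, _ = np.histogram(np.arange(d_max), bins=edges_frames)
        n_risk += counts
        if has_event:
            i = np.searchsorted(edges_frames, L - 1, side="right") - 1
            if 0 <= i < len(n_event):
                n_event[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(n_risk > 0, n_event / np.maximum(n_risk, 1), np.nan)
        se = np.sqrt(hazard * (1 - hazard) / np.maximum(n_risk, 1))
    return pd.DataFrame(
        {
            "bin_left_s": edges[:-1],
            "bin_right_s": edges[1:],
            "n_risk": n_risk.astype(int),
            "n_events": n_event.astype(int),
            "hazard": hazard,
            "se": np.where(n_risk > 0, se, np.nan),
            "empty": n_risk == 0,
        }
    )
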