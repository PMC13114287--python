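"""Lag-k covariates and design-matrix assembly for hazard models.

For each transition type (stop: exits from moving; start: exits from
resting) the design matrix has one row per *at-risk* (ant, frame): the ant
occupies the relevant state at frame ``t``, its dwell satisfies
``d(t) >= k`` so the lagged frame ``t - k`` lies inside the same bout, and
the state at ``t + 1`` is observed so the transition outcome can be
labelled.  All covariates are read at ``t - k`` — neighbourhood context
(local density, fraction of resting neighbours, speed difference, heading
dispersion), the log-dwell internal-state proxy, and optionally the
reconstructed pheromone concentration.  The label ``y`` is 1 iff the ant
leaves its state between ``t`` and ``t + 1``; it is the only quantity that
uses information after ``t - k``.

Isolated ants (no neighbour within the radius) receive neutral fills
(fraction resting 0.5, speed difference 0, heading dispersion cap/2) plus an
``isolated_flag`` covariate so the model can absorb the fill rather than
conditioning the risk set on neighbourhood occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .segmentation import ArenaSpec, MOVING, RESTING

__all__ = [
    "FeatureConfig",
    "NEIGHBOUR_COLUMNS",
    "local_density",
    "neighbour_indices",
    "fraction_resting",
    "speed_difference",
    "heading_dispersion",
    "pivot_dense",
    "compute_feature_arrays",
    "assemble_design",
]

#: the four neighbourhood covariates that constitute the "neighbours" model
#: (the isolated_flag indicator lives in the design matrix for diagnostics
#: and can be added explicitly as a feature, but the canonical neighbourhood
#: model is these four)
NEIGHBOUR_COLUMNS = [
    "local_density",
    "fraction_resting",
    "speed_difference",
    "heading_dispersion",
]

NEIGHBOUR_FEATURES = NEIGHBOUR_COLUMNS


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-construction parameters.

    Parameters
    ----------
    radius : float
        Neighbourhood radius in BL (closed ball, centre-to-centre).
    lag : int
        Predictor lag k in frames; covariates are read at t - k.
    heading_window : int
        Frames over which headings are estimated by displacement.
    heading_min_disp : float
        Minimum displacement (BL) for a heading to be defined.
    dispersion_cap : float
        Upper cap on circular standard deviation (radians); the neutral
        fill for undefined dispersions is half the cap.
    lag_dwell : bool
        If True (default) the dwell covariate is evaluated at t - k like
        every other covariate, i.e. log(d(t) - k + 1).
    """

    radius: float = 1.5
    lag: int = 3
    heading_window: int = 3
    heading_min_disp: float = 0.1
    dispersion_cap: float = 4.0
    lag_dwell: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.heading_window < 1:
            raise ValueError("heading_window must be at least 1 frame")


# ---------------------------------------------------------------------------
# single-frame reference operations (also the brute-force oracles' interface)
# ---------------------------------------------------------------------------

def neighbour_indices(positions: np.ndarray, focal: int, radius: float) -> np.ndarray:
    """Indices of ants within the closed ball of ``radius`` around ``focal``."""
    pos = np.asarray(positions, dtype=float)
    d = np.hypot(pos[:, 0] - pos[focal, 0], pos[:, 1] - pos[focal, 1])
    mask = d <= radius
    mask[focal] = False
    return np.where(mask)[0]


def local_density(positions: np.ndarray, focal: int, radius: float) -> float:
    """Neighbour count divided by the neighbourhood area pi * R**2 (ants/BL^2)."""
    n = len(neighbour_indices(positions, focal, radius))
    return n / (np.pi * radius**2)


def fraction_resting(states: np.ndarray, neighbours: np.ndarray) -> tuple[float, int]:
    """Proportion of neighbours resting; (0.5, flag=1) when isolated."""
    if len(neighbours) == 0:
        return 0.5, 1
    st = np.asarray(states)[neighbours]
    return float(np.mean(st == RESTING)), 0


def speed_difference(speeds: np.ndarray, focal: int, neighbours: np.ndarray) -> float:
    """Focal speed minus mean neighbour speed; 0 when no usable neighbour."""
    sp = np.asarray(speeds, dtype=float)
    nb = [j for j in neighbours if np.isfinite(sp[j])]
    if not nb or not np.isfinite(sp[focal]):
        return 0.0
    return float(sp[focal] - np.mean(sp[nb]))


def heading_dispersion(
    headings: np.ndarray,
    focal: int,
    neighbours: np.ndarray,
    cap: float = 4.0,
) -> float:
    """Circular standard deviation of neighbour-minus-focal heading differences.

    s = sqrt(-2 ln Rbar) with Rbar the mean resultant length, capped at
    ``cap``; the neutral fill ``cap / 2`` applies when the focal heading is
    undefined or no neighbour heading is defined.
    """
    h = np.asarray(headings, dtype=float)
    if not np.isfinite(h[focal]):
        return cap / 2.0
    diffs = [h[j] - h[focal] for j in neighbours if np.isfinite(h[j])]
    if not diffs:
        return cap / 2.0
    rbar = np.abs(np.mean(np.exp(1j * np.asarray(diffs))))
    if rbar >= 1.0:
        return 0.0
    return float(min(np.sqrt(-2.0 * np.log(max(rbar, 1e-300))), cap))


# ---------------------------------------------------------------------------
# dense pivots and vectorised feature computation
# ---------------------------------------------------------------------------

def pivot_dense(
    states: pd.DataFrame,
    traj: pd.DataFrame,
    arena: ArenaSpec | None = None,
) -> SimpleNamespace:
    """Pivot state/trajectory tables into dense (n_frames, n_ants) arrays.

    Positions are converted to BL and speeds to BL/s.  Missing ant-frames
    are NaN throughout.  Returns a namespace with ``ants`` (sorted ids),
    ``x, y, state, speed, dwell`` arrays and ``frame_rate``.
    """
    arena = arena or ArenaSpec()
    df = states.merge(
        traj[["ant_id", "frame", "x", "y"]],
        on=["ant_id", "frame"],
        how="left",
        validate="one_to_one",
        suffixes=("_s", ""),
    )
    if df["x"].isna().any():
        raise ValueError("states and trajectory tables have mismatched (ant, frame) indices")
    ants = np.sort(df["ant_id"].unique())
    ant_pos = {a: i for i, a in enumerate(ants)}
    T = int(df["frame"].max()) + 1
    N = len(ants)
    shape = (T, N)
    x = np.full(shape, np.nan)
    y = np.full(shape, np.nan)
    st = np.full(shape, np.nan)
    sp = np.full(shape, np.nan)
    dw = np.full(shape, np.nan)
    rows = df["frame"].to_numpy(int)
    cols = np.array([ant_pos[a] for a in df["ant_id"]])
    x[rows, cols] = df["x"].to_numpy(float) / arena.body_length_px
    y[rows, cols] = df["y"].to_numpy(float) / arena.body_length_px
    st[rows, cols] = df["state"].to_numpy(float)
    sp[rows, cols] = (
        df["speed"].to_numpy(float) / arena.body_length_px * arena.frame_rate
    )
    dw[rows, cols] = df["dwell"].to_numpy(float)
    return SimpleNamespace(
        ants=ants, x=x, y=y, state=st, speed=sp, dwell=dw,
        frame_rate=arena.frame_rate,
    )


def _headings(x: np.ndarray, y: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Displacement headings over ``heading_window`` frames; NaN if the
    displacement is below ``heading_min_disp`` or an endpoint is missing."""
    T, N = x.shape
    w = cfg.heading_window
    h = np.full((T, N), np.nan)
    if T <= w:
        return h
    dx = x[w:] - x[:-w]
    dy = y[w:] - y[:-w]
    disp = np.hypot(dx, dy)
    ok = np.isfinite(disp) & (disp >= cfg.heading_min_disp)
    h[w:][ok] = np.arctan2(dy[ok], dx[ok])
    return h


def compute_feature_arrays(
    x: np.ndarray,
    y: np.ndarray,
    state: np.ndarray,
    speed: np.ndarray,
    cfg: FeatureConfig,
    chunk: int | None = None,
    heading: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised per-frame neighbourhood features on dense arrays.

    All inputs are (n_frames, n_ants) with NaN for unobserved; positions in
    BL, speeds in BL/s.  Returns dense arrays for the five neighbourhood
    columns.  Frames are processed in chunks to bound the (frames, N, N)
    distance tensors.  ``heading`` overrides the displacement-based heading
    estimate (used by controls where motion channels must stay tied to ant
    identity while positions are permuted).
    """
    T, N = x.shape
    if chunk is None:
        chunk = max(1, 2_000_000 // max(1, N * N))
    area = np.pi * cfg.radius**2
    half_cap = cfg.dispersion_cap / 2.0
    if heading is None:
        heading = _headings(x, y, cfg)
    dens = np.zeros((T, N))
    frac = np.full((T, N), 0.5)
    sdif = np.zeros((T, N))
    disp = np.full((T, N), half_cap)
    iso = np.ones((T, N))
    hfill = np.where(np.isfinite(heading), heading, 0.0)
    spfill = np.where(np.isfinite(speed), speed, 0.0)
    for t0 in range(0, T, chunk):
        t1 = min(T, t0 + chunk)
        xs, ys = x[t0:t1], y[t0:t1]
        obs = np.isfinite(xs)
        dx = xs[:, :, None] - xs[:, None, :]
        dy = ys[:, :, None] - ys[:, None, :]
        with np.errstate(invalid="ignore"):
            nbr = (dx * dx + dy * dy) <= cfg.radius**2
        nbr &= obs[:, :, None] & obs[:, None, :]
        idx = np.arange(N)
        nbr[:, idx, idx] = False
        cnt = nbr.sum(axis=2)
        dens[t0:t1] = cnt / area
        iso[t0:t1] = (cnt == 0).astype(float)
        resting = (state[t0:t1] == RESTING) & obs
        nrest = (nbr & resting[:, None, :]).sum(axis=2)
        has = cnt > 0
        frac[t0:t1][has] = nrest[has] / cnt[has]
        # speed difference: neighbours with defined speed only
        spdef = np.isfinite(speed[t0:t1])
        nsp = nbr & spdef[:, None, :]
        ns = nsp.sum(axis=2)
        ssum = (np.where(nsp, spfill[t0:t1][:, None, :], 0.0)).sum(axis=2)
        okf = (ns > 0) & spdef
        sdif[t0:t1][okf] = speed[t0:t1][okf] - ssum[okf] / ns[okf]
        # heading dispersion over neighbours with defined headings
        hdef = np.isfinite(heading[t0:t1])
        nh = nbr & hdef[:, None, :] & hdef[:, :, None]
        m = nh.sum(axis=2)
        dh = hfill[t0:t1][:, None, :] - hfill[t0:t1][:, :, None]
        csum = np.where(nh, np.cos(dh), 0.0).sum(axis=2)
        ssin = np.where(nh, np.sin(dh), 0.0).sum(axis=2)
        okh = m > 0
        rbar = np.zeros_like(csum)
        rbar[okh] = np.hypot(csum[okh], ssin[okh]) / m[okh]
        rbar = np.clip(rbar, 1e-300, 1.0)
        s = np.sqrt(-2.0 * np.log(rbar))
        disp[t0:t1][okh] = np.minimum(s[okh], cfg.dispersion_cap)
    return {
        "local_density": dens,
        "fraction_resting": frac,
        "speed_difference": sdif,
        "heading_dispersion": disp,
        "isolated_flag": iso,
    }


def assemble_design(
    states: pd.DataFrame,
    traj: pd.DataFrame,
    transition_type: str,
    cfg: FeatureConfig | None = None,
    arena: ArenaSpec | None = None,
    phi: np.ndarray | pd.DataFrame | None = None,
    colony: str | None = None,
) -> pd.DataFrame:
    """Build the at-risk design matrix for one transition type.

    Parameters
    ----------
    states : DataFrame
        Output of :func:`anthazard.segmentation.classify_states`.
    traj : DataFrame
        Trajectory table sharing the (ant_id, frame) index.
    transition_type : {"stop", "start"}
        Stops model exits from the moving state, starts from resting.
    phi : optional
        Pheromone concentrations, either a dense (n_frames, n_ants) array
        aligned with the sorted ant order, or a DataFrame with columns
        ``ant_id, frame, phi``.

    Returns
    -------
    DataFrame
        One row per at-risk (ant, frame) with the covariates of
        ``NEIGHBOUR_COLUMNS``, ``log_dwell``, optional ``phi``, the label
        ``y`` and bookkeeping columns ``colony, ant_id, frame,
        transition_type``.
    """
    if transition_type not in ("stop", "start"):
        raise ValueError("transition_type must be 'stop' or 'start'")
    cfg = cfg or FeatureConfig()
    arena = arena or ArenaSpec()
    dense = pivot_dense(states, traj, arena)
    T, N = dense.x.shape
    k = cfg.lag
    feats = compute_feature_arrays(dense.x, dense.y, dense.state, dense.speed, cfg)
    s = MOVING if transition_type == "stop" else RESTING
    at_risk = np.zeros((T, N), dtype=bool)
    if T > 1:
        with np.errstate(invalid="ignore"):
            at_risk[:-1] = (
                (dense.state[:-1] == s)
                & (dense.dwell[:-1] >= k)
                & np.isfinite(dense.state[1:])
            )
    t_idx, a_idx = np.where(at_risk)
    y = (dense.state[t_idx + 1, a_idx] != s).astype(int)
    t_lag = t_idx - k
    d = dense.dwell[t_idx, a_idx]
    log_dwell = np.log((d - k if cfg.lag_dwell else d) + 1.0)
    if phi is not None:
        if isinstance(phi, pd.DataFrame):
            dense_phi = np.full((T, N), np.nan)
            ant_pos = {a: i for i, a in enumerate(dense.ants)}
            dense_phi[
                phi["frame"].to_numpy(int),
                np.array([ant_pos[a] for a in phi["ant_id"]]),
            ] = phi["phi"].to_numpy(float)
        else:
            dense_phi = np.asarray(phi, dtype=float)
            if dense_phi.shape != (T, N):
                raise ValueError("dense phi array does not match the (frame, ant) grid")
        phi_vals = dense_phi[t_lag, a_idx]
    design = pd.DataFrame(
        {
            "colony": colony if colony is not None else "C0",
            "ant_id": dense.ants[a_idx],
            "frame": t_idx,
            "transition_type": transition_type,
            "y": y,
            "local_density": feats["local_density"][t_lag, a_idx],
            "fraction_resting": feats["fraction_resting"][t_lag, a_idx],
            "speed_difference": feats["speed_difference"][t_lag, a_idx],
            "heading_dispersion": feats["heading_dispersion"][t_lag, a_idx],
            "isolated_flag": feats["isolated_flag"][t_lag, a_idx],
            "log_dwell": log_dwell,
        }
    )
    if phi is not None:
        design["phi"] = np.nan_to_num(phi_vals, nan=0.0)
    return design.sort_values(["ant_id", "frame"], kind="mergesort").reset_index(drop=True)
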