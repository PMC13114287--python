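"""Arrestant pheromone field reconstruction under an accumulation hypothesis.

Each ant continuously deposits chemical mass at its position; the field
diffuses and decays exponentially.  Per frame of duration ``dt`` an ant
deposits mass ``dt/tau`` through a truncated, renormalised Gaussian kernel;
the field is then blurred with variance ``2*D*dt`` (``D = ell**2/tau``) and
decayed by ``exp(-dt/tau)``.  With deposition and decay rates both ``1/tau``
each stationary ant contributes unit integrated mass at steady state.

The grid covers the arena's bounding square at ``grid_dx`` BL per cell and
stores mass per cell; diffusion uses a mass-conserving zero-flux (mirror)
boundary.  Downstream, sampled concentrations are residualised against local
density within cross-validation folds to isolate spatial memory from
instantaneous crowding, and a (tau, ell) grid search scores each candidate
field by the percent reduction in out-of-fold binomial deviance it brings
over a neighbours-only hazard model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

logger = logging.getLogger("anthazard")

__all__ = [
    "FieldParams",
    "PheromoneGrid",
    "run_field",
    "residualise_phi",
    "grid_search_phi",
]

#: candidate decay time constants (seconds) spanning minutes to an hour
DEFAULT_TAU_GRID = (60.0, 180.0, 300.0, 600.0, 900.0, 3600.0)
#: candidate diffusion lengths (body lengths)
DEFAULT_ELL_GRID = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the deposit-diffuse-decay field.

    Parameters
    ----------
    tau : float
        Exponential decay time constant in seconds.  Deposition rate is
        also ``1/tau`` so each ant carries unit steady-state mass.
    ell : float
        Diffusion length in BL; sets ``D = ell**2 / tau``.
    dep_sigma : float
        Radius (sd) of the Gaussian deposition kernel, BL.
    grid_dx : float
        Grid resolution, BL per cell.  Must not exceed ``dep_sigma``.
    """

    tau: float
    ell: float
    dep_sigma: float = 0.25
    grid_dx: float = 0.25

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.ell <= 0:
            raise ValueError("tau and ell must be positive")
        if self.dep_sigma <= 0 or self.grid_dx <= 0:
            raise ValueError("dep_sigma and grid_dx must be positive")
        if self.grid_dx > self.dep_sigma:
            raise ValueError("grid_dx must not exceed dep_sigma")

    @property
    def D(self) -> float:
        """Diffusion coefficient, BL^2 / s."""
        return self.ell**2 / self.tau


def _deposition_kernel(sigma_cells: float) -> np.ndarray:
    """Truncated (3 sigma) Gaussian kernel renormalised to unit mass."""
    half = max(1, int(np.ceil(3.0 * sigma_cells)))
    ax = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (ax / sigma_cells) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


class PheromoneGrid:
    """Gridded pheromone field over a square region of the arena.

    Parameters
    ----------
    params : FieldParams
    extent : tuple
        ``(xmin, xmax, ymin, ymax)`` in BL.
    dt : float
        Seconds per frame.
    """

    def __init__(self, params: FieldParams, extent: tuple[float, float, float, float], dt: float):
        self.params = params
        self.dt = float(dt)
        xmin, xmax, ymin, ymax = extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        dx = params.grid_dx
        self.origin = (float(xmin), float(ymin))
        self.nx = int(np.floor((xmax - xmin) / dx)) + 1
        self.ny = int(np.floor((ymax - ymin) / dx)) + 1
        self.grid = np.zeros((self.ny, self.nx))
        self._kernel = _deposition_kernel(params.dep_sigma / dx)
        self._blur_sigma = np.sqrt(2.0 * params.D * self.dt) / dx
        self.frame = 0
        self._clamp_warned = False

    def _to_cells(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (n, 2) BL positions to fractional (row, col) grid coordinates."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        col = (pos[:, 0] - self.origin[0]) / self.params.grid_dx
        row = (pos[:, 1] - self.origin[1]) / self.params.grid_dx
        out = (col < 0) | (col > self.nx - 1) | (row < 0) | (row > self.ny - 1)
        if out.any() and not self._clamp_warned:
            logger.warning(
                "%d position(s) outside the pheromone grid; clamped to nearest cell",
                int(out.sum()),
            )
            self._clamp_warned = True
        return np.clip(row, 0, self.ny - 1), np.clip(col, 0, self.nx - 1)

    def step(self, positions: np.ndarray | None) -> None:
        """Advance one frame: deposit at ant positions, diffuse, decay.

        The grid stores *concentration* (mass per BL^2), so sampled values
        are independent of the grid resolution; each deposit still adds
        exactly ``dt / tau`` of integrated mass.
        """
        p = self.params
        if positions is not None and len(positions) > 0:
            rows, cols = self._to_cells(positions)
            mass = self.dt / p.tau / p.grid_dx**2
            half = self._kernel.shape[0] // 2
            for r, c in zip(np.rint(rows).astype(int), np.rint(cols).astype(int)):
                r0, r1 = max(0, r - half), min(self.ny, r + half + 1)
                c0, c1 = max(0, c - half), min(self.nx, c + half + 1)
                w = self._kernel[
                    r0 - (r - half) : self._kernel.shape[0] - ((r + half + 1) - r1),
                    c0 - (c - half) : self._kernel.shape[1] - ((c + half + 1) - c1),
                ]
                self.grid[r0:r1, c0:c1] += mass * (w / w.sum())
        if self._blur_sigma > 0:
            self.grid = gaussian_filter(self.grid, self._blur_sigma, mode="reflect")
        self.grid *= np.exp(-self.dt / p.tau)
        np.maximum(self.grid, 0.0, out=self.grid)
        self.frame += 1

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the field at BL positions."""
        rows, cols = self._to_cells(positions)
        return map_coordinates(self.grid, [rows, cols], order=1, mode="nearest")

    def total_mass(self) -> float:
        """Integrated mass, i.e. concentration summed over cell areas."""
        return float(self.grid.sum() * self.params.grid_dx**2)


def run_field(
    x_bl: np.ndarray,
    y_bl: np.ndarray,
    params: FieldParams,
    frame_rate: float,
    extent: tuple[float, float, float, float] | None = None,
    deposit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve the field over dense (n_frames, n_ants) position arrays.

    NaN positions (unobserved ant-frames) neither deposit nor sample.
    ``deposit_mask`` optionally restricts deposition (e.g. to resting ants);
    by default every observed ant deposits.

    Returns
    -------
    ndarray
        phi with shape (n_frames, n_ants): the concentration at each ant's
        position after that frame's field update; NaN where unobserved.
    """
    T, N = x_bl.shape
    obs = np.isfinite(x_bl) & np.isfinite(y_bl)
    if extent is None:
        pad = 3.0 * params.dep_sigma + params.ell
        xmin, xmax = np.nanmin(x_bl), np.nanmax(x_bl)
        ymin, ymax = np.nanmin(y_bl), np.nanmax(y_bl)
        extent = (xmin - pad, xmax + pad, ymin - pad, ymax + pad)
    grid = PheromoneGrid(params, extent, dt=1.0 / frame_rate)
    phi = np.full((T, N), np.nan)
    for t in range(T):
        sel = obs[t]
        if deposit_mask is not None:
            dep = sel & deposit_mask[t]
        else:
            dep = sel
        pos_dep = np.column_stack([x_bl[t, dep], y_bl[t, dep]])
        grid.step(pos_dep if dep.any() else None)
        if sel.any():
            pos = np.column_stack([x_bl[t, sel], y_bl[t, sel]])
            phi[t, sel] = grid.sample(pos)
    return phi


def residualise_phi(
    phi: np.ndarray,
    density: np.ndarray,
    train_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Residuals of an OLS fit of phi on (intercept, local density).

    The regression is fitted on ``train_mask`` rows only (all rows when
    omitted) and applied everywhere, so held-out rows can be residualised
    with training coefficients inside a cross-validation fold.  Zero-variance
    density degenerates to centring phi on its training mean.
    """
    phi = np.asarray(phi, dtype=float)
    density = np.asarray(density, dtype=float)
    if phi.shape != density.shape:
        raise ValueError("phi and density must be paired vectors")
    tm = np.ones(len(phi), dtype=bool) if train_mask is None else np.asarray(train_mask, bool)
    if tm.sum() == 0:
        raise ValueError("empty training mask")
    if np.std(density[tm]) == 0:
        return phi - phi[tm].mean()
    X = np.column_stack([np.ones(len(phi)), density])
    beta, *_ = np.linalg.lstsq(X[tm], phi[tm], rcond=None)
    return phi - X @ beta


def grid_search_phi(
    states: pd.DataFrame,
    traj: pd.DataFrame,
    tau_grid=DEFAULT_TAU_GRID,
    ell_grid=DEFAULT_ELL_GRID,
    transition_types: tuple[str, ...] = ("stop", "start"),
    feature_config=None,
    arena=None,
    model_spec=None,
) -> pd.DataFrame:
    """Out-of-fold deviance improvement of phi over a neighbours-only model.

    For every (tau, ell) pair the field is reconstructed from the
    trajectory, sampled at lag-k positions of the at-risk rows,
    residualised against local density within each training fold, and a
    {neighbours + phi_resid} hazard model is compared with the nested
    {neighbours} baseline on identical folds and sampled rows.

    Returns
    -------
    DataFrame
        Columns ``tau, ell, transition_type, pct_deviance_improvement``.
    """
    # imported here to avoid a circular module dependency
    from .covariates import FeatureConfig, assemble_design, pivot_dense
    from .hazard import ModelSpec, _oof_deviance, incidence_density_sample

    if len(tau_grid) == 0 or len(ell_grid) == 0:
        raise ValueError("tau and ell grids must be non-empty")
    cfg = feature_config or FeatureConfig()
    spec = model_spec or ModelSpec()
    dense = pivot_dense(states, traj, arena)
    rows = []
    for tt in transition_types:
        base_design = assemble_design(states, traj, tt, cfg=cfg, arena=arena)
        sampled = incidence_density_sample(base_design, spec.ratio, spec.seed)
        dev_base = _oof_deviance(sampled, ("neighbours",), spec)
        for tau in tau_grid:
            for ell in ell_grid:
                params = FieldParams(float(tau), float(ell))
                phi = run_field(dense.x, dense.y, params, dense.frame_rate)
                design = assemble_design(
                    states, traj, tt, cfg=cfg, arena=arena, phi=phi
                )
                s2 = incidence_density_sample(design, spec.ratio, spec.seed)
                dev_phi = _oof_deviance(s2, ("neighbours", "phi"), spec)
                rows.append(
                    {
                        "tau": tau,
                        "ell": ell,
                        "transition_type": tt,
                        "pct_deviance_improvement": 100.0 * (dev_base - dev_phi) / dev_base,
                    }
                )
    return pd.DataFrame(rows)
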