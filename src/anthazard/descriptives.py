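"""Colony-level descriptive summaries: activity fraction and spatial clustering.

Clusters are density-based (DBSCAN with an epsilon-neighbourhood in BL and a
minimum cluster size): dense groups of resting ants are the macroscopic
outcome whose microscopic drivers the hazard models interrogate, so these
series are descriptive context, not covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = ["activity_fraction", "cluster_metrics"]


def _rolling_mean(series: pd.Series, window: int) -> pd.Series:
    # centred, shrinking toward the edges
    return series.rolling(window, center=True, min_periods=1).mean()


def activity_fraction(
    states: pd.DataFrame,
    frame_rate: float = 10.0,
    window_s: float = 5.0,
) -> pd.Series:
    """Fraction of known-state ants moving per frame, smoothed.

    Parameters
    ----------
    states : DataFrame
        ``ant_id, frame, state`` with state 1/0/NaN.
    window_s : float
        Width of the centred rolling mean in seconds (shrinks at edges).
    """
    known = states.dropna(subset=["state"])
    frac = known.groupby("frame")["state"].mean()
    frac = frac.reindex(range(int(states["frame"].max()) + 1))
    window = max(1, int(round(window_s * frame_rate)))
    return _rolling_mean(frac, window).rename("fraction_moving")


def cluster_metrics(
    traj_bl: pd.DataFrame,
    eps: float = 1.5,
    min_size: int = 3,
    frame_rate: float = 10.0,
    smooth_s: float = 5.0,
    return_labels: bool = False,
):
    """Per-frame DBSCAN cluster count and clustered fraction.

    Parameters
    ----------
    traj_bl : DataFrame
        ``ant_id, frame, x, y`` with positions in BL.
    eps : float
        Neighbourhood radius in BL.
    min_size : int
        Minimum cluster size (DBSCAN ``min_samples``, self included).

    Returns
    -------
    DataFrame
        ``frame, n_clusters, fraction_clustered`` (smoothed with a centred
        rolling mean over ``smooth_s`` seconds); optionally also a labels
        DataFrame ``ant_id, frame, cluster`` with -1 for noise.
    """
    rows = []
    label_rows = []
    for frame, grp in traj_bl.sort_values(["frame", "ant_id"]).groupby("frame"):
        pts = grp[["x", "y"]].to_numpy()
        n_obs = len(pts)
        if n_obs < min_size:
            rows.append((frame, 0, 0.0))
            if return_labels:
                label_rows.extend((a, frame, -1) for a in grp["ant_id"])
            continue
        labels = DBSCAN(eps=eps, min_samples=min_size).fit(pts).labels_
        n_clusters = int(labels.max()) + 1 if labels.max() >= 0 else 0
        frac = float(np.mean(labels >= 0))
        rows.append((frame, n_clusters, frac))
        if return_labels:
            label_rows.extend(
                (a, frame, int(l)) for a, l in zip(grp["ant_id"], labels)
            )
    out = pd.DataFrame(rows, columns=["frame", "n_clusters", "fraction_clustered"])
    window = max(1, int(round(smooth_s * frame_rate)))
    out["n_clusters"] = _rolling_mean(out["n_clusters"], window)
    out["fraction_clustered"] = _rolling_mean(out["fraction_clustered"], window)
    if return_labels:
        return out, pd.DataFrame(label_rows, columns=["ant_id", "frame", "cluster"])
    return out
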