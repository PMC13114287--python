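"""Speed-based moving/resting segmentation of ant trajectories.

Raw trajectories give per-frame positions (pixels).  This module turns them
into instantaneous speeds, a two-state behavioural classification with
minimum-duration filtering, dwell times (frames since state entry), bout
tables and stop/start transition events.

States are coded ``1`` = moving, ``0`` = resting, ``NaN`` = unknown (frames
whose speed cannot be computed, i.e. an ant's first observed frame or a frame
following a tracking gap).  Unknown frames never contribute to bouts, and
dwell resets after every gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MOVING = 1
RESTING = 0

__all__ = [
    "ArenaSpec",
    "compute_speeds",
    "classify_states",
    "extract_bouts",
    "detect_transitions",
    "segment",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Spatial/temporal calibration of a recording.

    Parameters
    ----------
    scale : float
        mm per pixel.
    body_length_px : float
        Ant body length in pixels; 1 BL (body length) is the internal
        spatial unit of all downstream features.
    frame_rate : float
        Frames per second.
    """

    scale: float = 0.083
    body_length_px: float = 30.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.body_length_px <= 0 or self.frame_rate <= 0:
            raise ValueError("ArenaSpec fields must all be positive")

    @property
    def dt(self) -> float:
        """Seconds per frame."""
        return 1.0 / self.frame_rate


def compute_speeds(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-frame instantaneous speed as the backward one-frame displacement.

    Parameters
    ----------
    traj : DataFrame
        Columns ``ant_id, frame, x, y`` (pixels), at most one row per
        (ant_id, frame).

    Returns
    -------
    DataFrame
        Columns ``ant_id, frame, x, y, speed`` with speed in pixels/frame;
        NaN at an ant's first observed frame and immediately after gaps.
    """
    required = {"ant_id", "frame", "x", "y"}
    missing = required - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    if traj.duplicated(["ant_id", "frame"]).any():
        raise ValueError("duplicate (ant_id, frame) rows in trajectory")
    out = traj.sort_values(["ant_id", "frame"], kind="mergesort").reset_index(drop=True)
    dx = out.groupby("ant_id", sort=False)["x"].diff()
    dy = out.groupby("ant_id", sort=False)["y"].diff()
    dframe = out.groupby("ant_id", sort=False)["frame"].diff()
    speed = np.hypot(dx, dy)
    speed[dframe != 1] = np.nan
    out["speed"] = speed
    return out


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values -> list of (state, start, stop) index runs."""
    runs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((int(values[start]), start, i))
            start = i
    return runs


def filter_min_duration(labels: np.ndarray, min_rest: int, min_move: int) -> np.ndarray:
    """Enforce minimum bout durations on a 0/1 label sequence.

    Repeatedly finds the shortest bout below its state's minimum (ties ->
    earliest), relabels it to the state of its longer flanking bout (ties ->
    the previous bout's state), merges, and iterates until every bout meets
    its minimum.  A sequence that collapses to a single bout is returned
    as-is even if that bout is below minimum (there is nothing to merge it
    into), which keeps the filter idempotent.
    """
    if min_rest < 1 or min_move < 1:
        raise ValueError("minimum durations must be at least 1 frame")
    if len(labels) == 0:
        return labels.copy()
    minima = {RESTING: min_rest, MOVING: min_move}
    bouts = [[s, stop - start] for s, start, stop in _runs(np.asarray(labels))]
    while len(bouts) > 1:
        short = [
            (length, idx)
            for idx, (s, length) in enumerate(bouts)
            if length < minima[s]
        ]
        if not short:
            break
        _, i = min(short)
        prev_len = bouts[i - 1][1] if i > 0 else -1
        next_len = bouts[i + 1][1] if i + 1 < len(bouts) else -1
        if prev_len >= next_len:  # ties -> previous bout's state
            bouts[i][0] = bouts[i - 1][0]
        else:
            bouts[i][0] = bouts[i + 1][0]
        merged: list[list[int]] = []
        for s, length in bouts:
            if merged and merged[-1][0] == s:
                merged[-1][1] += length
            else:
                merged.append([s, length])
        bouts = merged
    return np.concatenate([np.full(length, s, dtype=int) for s, length in bouts])


def classify_states(
    speeds: pd.DataFrame,
    threshold: float = 3.0,
    min_rest: int = 10,
    min_move: int = 5,
) -> pd.DataFrame:
    """Classify frames as moving/resting and apply minimum-duration filtering.

    Parameters
    ----------
    speeds : DataFrame
        Output of :func:`compute_speeds`.
    threshold : float
        Speed threshold in pixels/frame; moving iff speed > threshold.
    min_rest, min_move : int
        Minimum bout durations in frames (defaults 10 and 5 frames, i.e.
        1.0 s and 0.5 s at 10 fps).

    Returns
    -------
    DataFrame
        ``ant_id, frame, x, y, speed, state, dwell`` where state is
        1 (moving), 0 (resting) or NaN (unknown) and dwell counts frames
        since bout entry (0 at the entry frame, NaN where state is unknown).
    """
    if threshold <= 0:
        raise ValueError("speed threshold must be positive")
    if min_rest < 1 or min_move < 1:
        raise ValueError("minimum durations must be at least 1 frame")
    out = speeds.sort_values(["ant_id", "frame"], kind="mergesort").reset_index(drop=True)
    state = np.where(out["speed"] > threshold, MOVING, RESTING).astype(float)
    state[out["speed"].isna()] = np.nan
    frames = out["frame"].to_numpy()
    ants = out["ant_id"].to_numpy()
    # contiguous runs of known state within one ant: boundaries at ant change,
    # frame discontinuity, or unknown frames
    known = ~np.isnan(state)
    new_block = np.ones(len(out), dtype=bool)
    if len(out) > 1:
        same_ant = ants[1:] == ants[:-1]
        contiguous = frames[1:] == frames[:-1] + 1
        new_block[1:] = ~(same_ant & contiguous)
    block = np.cumsum(new_block)
    for _, idx in pd.Series(np.arange(len(out))[known]).groupby(block[known]):
        ii = idx.to_numpy()
        state[ii] = filter_min_duration(state[ii].astype(int), min_rest, min_move)
    out["state"] = state
    # dwell: frames since entry of the current bout
    dwell = np.full(len(out), np.nan)
    bout_break = new_block.copy()
    if len(out) > 1:
        bout_break[1:] |= state[1:] != state[:-1]
    bout_break |= ~known
    bout_id = np.cumsum(bout_break)
    pos = np.arange(len(out))
    bout_start = pd.Series(pos).groupby(bout_id).transform("min").to_numpy()
    dwell[known] = (pos - bout_start)[known]
    out["dwell"] = dwell
    return out


def extract_bouts(states: pd.DataFrame) -> pd.DataFrame:
    """Maximal constant-state runs as half-open frame intervals.

    Returns
    -------
    DataFrame
        ``ant_id, state, start_frame, end_frame, duration`` with
        end_frame exclusive and duration = end - start in frames.
    """
    rows = []
    if len(states) == 0:
        return pd.DataFrame(
            columns=["ant_id", "state", "start_frame", "end_frame", "duration"]
        )
    df = states.sort_values(["ant_id", "frame"], kind="mergesort")
    for ant, grp in df.groupby("ant_id", sort=True):
        fr = grp["frame"].to_numpy()
        st = grp["state"].to_numpy(dtype=float)
        idx = np.where(~np.isnan(st))[0]
        if len(idx) == 0:
            continue
        # a bout breaks at any skipped row, frame discontinuity or state change
        brk = (
            (np.diff(idx) != 1)
            | (np.diff(fr[idx]) != 1)
            | (np.diff(st[idx]) != 0)
        )
        run_starts = np.concatenate([[0], np.where(brk)[0] + 1])
        run_ends = np.concatenate([np.where(brk)[0], [len(idx) - 1]])
        for a, b in zip(run_starts, run_ends):
            rows.append(
                (ant, int(st[idx[a]]), int(fr[idx[a]]), int(fr[idx[b]]) + 1)
            )
    bouts = pd.DataFrame(rows, columns=["ant_id", "state", "start_frame", "end_frame"])
    bouts["duration"] = bouts["end_frame"] - bouts["start_frame"]
    return bouts


def detect_transitions(bouts: pd.DataFrame) -> pd.DataFrame:
    """Stop/start events from adjacent contiguous bout pairs.

    A moving bout immediately followed (same ant, contiguous frames) by a
    resting bout emits a ``stop`` at the last frame of the moving bout;
    the reverse emits a ``start``.  Bout pairs separated by unknown frames
    emit nothing.
    """
    rows = []
    for ant, grp in bouts.sort_values(["ant_id", "start_frame"]).groupby("ant_id", sort=True):
        g = grp.reset_index(drop=True)
        for i in range(len(g) - 1):
            if g.loc[i, "end_frame"] == g.loc[i + 1, "start_frame"]:
                kind = "stop" if g.loc[i, "state"] == MOVING else "start"
                rows.append((ant, int(g.loc[i, "end_frame"]) - 1, kind))
    return pd.DataFrame(rows, columns=["ant_id", "frame", "type"])


def segment(
    traj: pd.DataFrame,
    threshold: float = 3.0,
    min_rest: int = 10,
    min_move: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: trajectory -> (states, bouts, events)."""
    states = classify_states(compute_speeds(traj), threshold, min_rest, min_move)
    bouts = extract_bouts(states)
    events = detect_transitions(bouts)
    return states, bouts, events
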