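"""Windowed kinematic parameters: position, speed, round trips.

All parameter means are taken over 15-min analysis windows (minutes 10-25
before odor injection, 37-52 after).  Mean X position uses the normalized
coordinates; mean speed uses the cm coordinates with a 5-s time step
(Euclidean displacement between step anchors divided by the step); round
trips count crossings of the +/-0.5 fraction of each axis half-extent,
divided by two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory, TrialDesign


class WindowError(ValueError):
    """An analysis window is empty or not covered by the track."""


@dataclass
class WindowKinematics:
    """Kinematic parameter means for one 15-min analysis window."""

    window: tuple[float, float]          # (start_min, end_min)
    mean_position_x: float               # unitless, in [-1, 1]
    mean_speed: float                    # cm/s
    round_trips_x: float                 # crossings / 2; multiples of 0.5
    round_trips_y: float


def window_slice(traj: Trajectory, start_min: float, end_min: float) -> Trajectory:
    """Samples with start <= t < end (minutes; half-open window)."""
    if start_min >= end_min:
        raise WindowError(f"empty window ({start_min}, {end_min})")
    mask = (traj.t >= start_min * 60.0) & (traj.t < end_min * 60.0)
    if not mask.any():
        raise WindowError(
            f"window ({start_min}, {end_min}) min does not intersect track "
            f"span [{traj.t[0] / 60:.2f}, {traj.t[-1] / 60:.2f}] min"
        )
    return Trajectory(
        fish_id=traj.fish_id, t=traj.t[mask], xc=traj.xc[mask],
        yc=traj.yc[mask], x_cm=traj.x_cm[mask], y_cm=traj.y_cm[mask],
        frame_rate=traj.frame_rate, y_half_norm=traj.y_half_norm,
        odor_is_plus_x=traj.odor_is_plus_x,
    )


def mean_position_x(win: Trajectory) -> float:
    """Arithmetic mean of Xc over every sample in the window."""
    if len(win) == 0:
        raise WindowError("empty window")
    return float(np.mean(win.xc))


def mean_speed(win: Trajectory, step_s: float = 5.0) -> float:
    """Mean speed over non-overlapping step anchors (cm/s).

    Anchors are placed every ``step_s`` seconds from the window start; a
    partial final step is discarded.  Speed per step is the straight-line
    displacement between anchors divided by the step duration.
    """
    if len(win) == 0:
        raise WindowError("empty window")
    stride = int(round(step_s * win.frame_rate))
    if stride < 1:
        raise WindowError("step shorter than one frame")
    idx = np.arange(0, len(win), stride)
    if idx.size < 2:
        raise WindowError("window spans fewer than 2 speed-step anchors")
    dx = np.diff(win.x_cm[idx])
    dy = np.diff(win.y_cm[idx])
    return float(np.mean(np.hypot(dx, dy)) / step_s)


def _crossings(x: np.ndarray, h: float) -> int:
    """Number of sample pairs strictly straddling level h."""
    s = np.sign(x - h)
    # samples exactly on the threshold never create a strict sign change
    return int(np.sum(s[:-1] * s[1:] < 0))


def round_trips(win: Trajectory, axis: str = "X",
                threshold_frac: float = 0.5,
                literal_y_threshold: bool = False) -> float:
    """Round trips along an axis: threshold crossings divided by two.

    Thresholds sit at ``threshold_frac`` of the axis half-extent: +/-0.5
    in X and +/-0.37 in Y by default.  ``literal_y_threshold`` places the
    Y thresholds at the literal +/-0.5 instead (68% of the Y half-extent
    0.74), the alternative reading of the counting rule.
    """
    if len(win) == 0:
        raise WindowError("empty window")
    if axis.upper() == "X":
        x, h = win.xc, threshold_frac * 1.0
    elif axis.upper() == "Y":
        x = win.yc
        h = 0.5 if literal_y_threshold else threshold_frac * win.y_half_norm
    else:
        raise ValueError(f"axis must be X or Y, got {axis!r}")
    return (_crossings(x, h) + _crossings(x, -h)) / 2.0


def window_kinematics(win: Trajectory, window: tuple[float, float],
                      step_s: float = 5.0, threshold_frac: float = 0.5,
                      literal_y_threshold: bool = False) -> WindowKinematics:
    return WindowKinematics(
        window=window,
        mean_position_x=mean_position_x(win),
        mean_speed=mean_speed(win, step_s=step_s),
        round_trips_x=round_trips(win, "X", threshold_frac),
        round_trips_y=round_trips(win, "Y", threshold_frac,
                                  literal_y_threshold=literal_y_threshold),
    )


def summarize_windows(traj: Trajectory, trial: TrialDesign,
                      step_s: float = 5.0, threshold_frac: float = 0.5,
                      literal_y_threshold: bool = False
                      ) -> tuple[WindowKinematics, WindowKinematics]:
    """Kinematics for the before (10-25 min) and after (37-52 min) windows."""
    out = []
    for name, (lo, hi) in (("before", trial.window_before),
                           ("after", trial.window_after)):
        try:
            win = window_slice(traj, lo, hi)
            out.append(window_kinematics(
                win, (lo, hi), step_s=step_s, threshold_frac=threshold_frac,
                literal_y_threshold=literal_y_threshold))
        except WindowError as e:
            raise WindowError(f"{name} window: {e}") from e
    return out[0], out[1]
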