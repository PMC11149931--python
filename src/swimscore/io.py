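"""Tracker file I/O and coordinate recoding.

Raw tracker output is a per-fish CSV time series of X/Y coordinates at
30 samples/s over a 1-hr recording, in both pixels and cm (columns
``frame,t_s,x_px,y_px,x_cm,y_cm``).  Pixel coordinates are recoded into a
centered, odor-oriented frame: the box center maps to 0, the odor-side
short wall to Xc = +1 and the water-side wall to Xc = -1; the long walls
map to Yc = +/-0.74, the box width-to-length ratio (8.5/11.5).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["frame", "t_s", "x_px", "y_px", "x_cm", "y_cm"]

SUMMARY_COLUMNS = [
    "fish_id", "morph", "day", "odor", "conc_M", "odor_side",
    "pos_before", "pos_after", "speed_before", "speed_after",
    "rtx_before", "rtx_after", "rty_before", "rty_after",
    "patterns_before", "patterns_after",
    "idx_pos", "idx_speed", "idx_rt", "idx_pattern", "score", "responder",
]


class TrackFormatError(ValueError):
    """Malformed track file (bad header or schema)."""


class TrackValidationError(ValueError):
    """Track content violates an invariant (e.g. non-monotonic time)."""


class GeometryError(ValueError):
    """Degenerate or inconsistent arena geometry."""


class SummarySchemaError(ValueError):
    """Per-fish summary record is missing a required field."""


@dataclass
class RawTrack:
    """One fish's tracker output: time plus pixel and cm coordinates."""

    fish_id: str
    t: np.ndarray          # seconds, strictly increasing
    x_px: np.ndarray
    y_px: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    frame_rate: float = 30.0
    n_dropped: int = 0     # unparseable rows removed at read time

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise TrackValidationError("frame_rate must be > 0")
        self.t = np.asarray(self.t, dtype=float)
        for name in ("x_px", "y_px", "x_cm", "y_cm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.t.size == 0:
            raise TrackValidationError("track has no samples")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise TrackValidationError(
                f"time not strictly increasing at row {int(bad[0]) + 1}"
            )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BoxGeometry:
    """Test-box geometry: physical size plus the pixel frame of the arena.

    ``px_x`` / ``px_y`` are the pixel extents (min, max) of the arena along
    each image axis.  They may be omitted and calibrated from a track's own
    min/max via :meth:`with_extents_from`, a fallback for tracks from fish
    that did visit all four walls.
    """

    length_cm: float = 11.5
    width_cm: float = 8.5
    water_volume_ml: float = 150.0
    px_x: tuple[float, float] | None = None
    px_y: tuple[float, float] | None = None
    x_half_norm: float = 1.0
    y_half_norm: float = 0.74

    def __post_init__(self) -> None:
        if not (self.length_cm > self.width_cm > 0):
            raise GeometryError("require length_cm > width_cm > 0")
        ratio = self.width_cm / self.length_cm
        if abs(self.length_cm - 11.5) < 1e-9 and abs(self.width_cm - 8.5) < 1e-9:
            if abs(self.y_half_norm - ratio) > 0.01:
                raise GeometryError(
                    f"y_half_norm {self.y_half_norm} inconsistent with "
                    f"width/length {ratio:.4f}"
                )

    @classmethod
    def from_corners(cls, corners: list[tuple[float, float]], **kw) -> "BoxGeometry":
        """Build from the four pixel corners of the arena."""
        if len(corners) != 4:
            raise GeometryError("need exactly 4 corner points")
        xs = [c[0] for c in corners]
        ys = [c[1] for c in corners]
        return cls(px_x=(min(xs), max(xs)), px_y=(min(ys), max(ys)), **kw)

    def with_extents_from(self, raw: RawTrack) -> "BoxGeometry":
        """Fallback calibration: pixel extents from the track's own range."""
        logger.warning(
            "geometry: calibrating pixel extents from track %s min/max",
            raw.fish_id,
        )
        return replace(
            self,
            px_x=(float(raw.x_px.min()), float(raw.x_px.max())),
            px_y=(float(raw.y_px.min()), float(raw.y_px.max())),
        )


@dataclass
class TrialDesign:
    """Metadata for one fish x day x odor trial."""

    fish_id: str
    morph: str = "SF"                 # SF | CF | F2
    odor: str = "water"
    syringe_concentration: float = 0.0   # mol/L in the syringe
    odor_side: str = "right"          # left | right (pixel-frame side)
    stim_min: float = 30.0            # injection time on the edited timeline
    window_before: tuple[float, float] = (10.0, 25.0)
    window_after: tuple[float, float] = (37.0, 52.0)
    day: int = 1

    def __post_init__(self) -> None:
        if self.morph not in {"SF", "CF", "F2"}:
            raise ValueError(f"unknown morph {self.morph!r}")
        if self.odor_side not in {"left", "right"}:
            raise ValueError(f"odor_side must be left/right, got {self.odor_side!r}")
        b, a = self.window_before, self.window_after
        for lo, hi in (b, a):
            if not (0 <= lo < hi <= 60):
                raise ValueError("analysis windows must lie within [0, 60] min")
        if b[1] > self.stim_min:
            raise ValueError("before-window must end at or before stim_min")
        if a[0] < self.stim_min:
            raise ValueError("after-window must start at or after stim_min")


def validate_day_alternation(trials: list[TrialDesign]) -> None:
    """Check that odor side alternates across consecutive days per fish."""
    by_fish: dict[str, list[TrialDesign]] = {}
    for tr in trials:
        by_fish.setdefault(tr.fish_id, []).append(tr)
    for fid, ts in by_fish.items():
        ts = sorted(ts, key=lambda t: t.day)
        for prev, cur in zip(ts, ts[1:]):
            if cur.day == prev.day + 1 and cur.odor_side == prev.odor_side:
                raise ValueError(
                    f"fish {fid}: odor side not reversed between day "
                    f"{prev.day} and day {cur.day}"
                )


@dataclass
class Trajectory:
    """Recoded track: unitless centered coordinates, odor side at +X.

    The cm coordinates are carried along because speed is computed from
    them (position and round trips use the normalized ones).
    """

    fish_id: str
    t: np.ndarray
    xc: np.ndarray
    yc: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    frame_rate: float = 30.0
    y_half_norm: float = 0.74
    odor_is_plus_x: bool = True
    n_clipped: int = 0

    def __len__(self) -> int:
        return self.t.size


def read_track(stream, fish_id: str = "", frame_rate: float = 30.0,
               dialect: str = "csv") -> RawTrack:
    """Parse a tracker CSV into a :class:`RawTrack`.

    Rows whose coordinates fail to parse (e.g. ``NaN``) are dropped and
    counted; the drop count is logged and kept on the track.
    """
    if isinstance(stream, (str, bytes)):
        stream = _io.StringIO(stream if isinstance(stream, str) else stream.decode())
    df = pd.read_csv(stream)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track file missing column(s): {', '.join(missing)}")
    if df.shape[0] == 0:
        raise TrackFormatError("track file has no data rows")
    coords = df[["x_px", "y_px", "x_cm", "y_cm"]].apply(pd.to_numeric, errors="coerce")
    ok = coords.notna().all(axis=1) & pd.to_numeric(df["t_s"], errors="coerce").notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_track %s: dropped %d unparseable rows", fish_id, n_dropped)
    kept = df.loc[ok]
    return RawTrack(
        fish_id=fish_id,
        t=kept["t_s"].to_numpy(float),
        x_px=kept["x_px"].to_numpy(float),
        y_px=kept["y_px"].to_numpy(float),
        x_cm=kept["x_cm"].to_numpy(float),
        y_cm=kept["y_cm"].to_numpy(float),
        frame_rate=frame_rate,
        n_dropped=n_dropped,
    )


def write_track(raw: RawTrack, stream) -> None:
    """Write a RawTrack in the documented CSV dialect."""
    df = pd.DataFrame({
        "frame": np.arange(len(raw)),
        "t_s": raw.t,
        "x_px": raw.x_px,
        "y_px": raw.y_px,
        "x_cm": raw.x_cm,
        "y_cm": raw.y_cm,
    })
    df.to_csv(stream, index=False, float_format="%.6f")


def _axis_map(values: np.ndarray, extent: tuple[float, float],
              half_norm: float) -> np.ndarray:
    lo, hi = extent
    if hi <= lo:
        raise GeometryError(f"degenerate pixel extent ({lo}, {hi})")
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return half_norm * (values - center) / half


def recode(raw: RawTrack, geom: BoxGeometry, trial: TrialDesign,
           clip_tol: float = 0.05) -> Trajectory:
    """Affine-map pixel coordinates into the centered odor-oriented frame.

    Coordinates landing beyond the walls by up to ``clip_tol`` (tracking
    jitter) are clipped to the wall and counted; larger excursions also
    clip but are logged loudly.
    """
    if geom.px_x is None or geom.px_y is None:
        geom = geom.with_extents_from(raw)
    xc = _axis_map(raw.x_px, geom.px_x, geom.x_half_norm)
    yc = _axis_map(raw.y_px, geom.px_y, geom.y_half_norm)
    if trial.odor_side == "left":
        xc = -xc
    out_x = np.abs(xc) > geom.x_half_norm
    out_y = np.abs(yc) > geom.y_half_norm
    n_clipped = int(out_x.sum() + out_y.sum())
    far = (np.abs(xc) > geom.x_half_norm + clip_tol).sum() + \
          (np.abs(yc) > geom.y_half_norm + clip_tol).sum()
    if far:
        logger.warning("recode %s: %d samples beyond walls by more than "
                       "clip_tol=%.3f", raw.fish_id, int(far), clip_tol)
    elif n_clipped:
        logger.info("recode %s: clipped %d samples to walls", raw.fish_id, n_clipped)
    xc = np.clip(xc, -geom.x_half_norm, geom.x_half_norm)
    yc = np.clip(yc, -geom.y_half_norm, geom.y_half_norm)
    return Trajectory(
        fish_id=raw.fish_id, t=raw.t.copy(), xc=xc, yc=yc,
        x_cm=raw.x_cm.copy(), y_cm=raw.y_cm.copy(),
        frame_rate=raw.frame_rate, y_half_norm=geom.y_half_norm,
        odor_is_plus_x=True, n_clipped=n_clipped,
    )


def unrecode(traj: Trajectory, geom: BoxGeometry, trial: TrialDesign
             ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`recode` on the box interior: back to pixels."""
    if geom.px_x is None or geom.px_y is None:
        raise GeometryError("unrecode requires explicit pixel extents")
    xc = -traj.xc if trial.odor_side == "left" else traj.xc

    def inv(v, extent, half_norm):
        lo, hi = extent
        center, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return center + v * half / half_norm

    return (inv(xc, geom.px_x, geom.x_half_norm),
            inv(traj.yc, geom.px_y, geom.y_half_norm))


def write_summary_table(rows: list[dict], stream) -> None:
    """Write per-fish summary records as a TSV, one row per fish x condition.

    Every record must carry every column of the documented schema; floats
    are written to 6 decimals so a write-then-read cycle is the identity.
    """
    for rec in rows:
        for col in SUMMARY_COLUMNS:
            if col not in rec or rec[col] is None:
                raise SummarySchemaError(
                    f"record for fish {rec.get('fish_id', '?')!r} missing "
                    f"field {col!r}"
                )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(stream, sep="\t", index=False, float_format="%.6f")


def read_summary_table(stream) -> pd.DataFrame:
    """Read a summary TSV written by :func:`write_summary_table`."""
    if isinstance(stream, str) and "\t" in stream:
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SummarySchemaError(f"summary table missing column(s): {missing}")
    df["responder"] = df["responder"].astype(bool)
    return df


def dilution_factor(injected_ml: float = 0.5, zone_ml: float = 50.0) -> float:
    """Dilution factor of the syringe solution in the odor-injection zone.

    The 150 ml box is virtually split into thirds, so the odor zone holds
    50 ml; injecting 0.5 ml of syringe solution dilutes it ~100-fold
    (zone/injected; the refinement (zone+injected)/injected = 101 is
    within the assay's precision and not used).
    """
    if injected_ml <= 0 or zone_ml <= 0:
        raise ValueError("volumes must be positive")
    return zone_ml / injected_ml
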