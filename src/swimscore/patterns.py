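"""Swim-pattern taxonomy, rule-based window classification, cohort tables.

Larval fish express a small repertoire of baseline swim modes: random
swim (R), wall following (WF), circling (C), and thigmotaxis — stereotyped
back-and-forth shuttling along a single wall, along the long axis (TX) or
the short axis (TY).  A fish's pattern set for an analysis window is the
set of elementary modes it expressed, possibly more than one.

In the original assay the labels were assigned by eye from track plots;
here an explicit rule-based classifier reproduces that call from segment
statistics (wall-band occupancy, winding about the box center, heading
rotation, along-wall reversals), and manual annotations can be loaded and
used instead wherever a PatternSet is consumed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import Trajectory

PATTERN_ORDER = ("R", "WF", "C", "TX", "TY")


class PatternParseError(ValueError):
    """Unknown or empty pattern label in an annotation file."""


@dataclass(frozen=True)
class PatternSet:
    """A nonempty subset of {R, WF, C, TX, TY} with its provenance."""

    labels: frozenset
    provenance: str = "rule-based"     # or "manual"

    def __post_init__(self):
        if not self.labels:
            raise ValueError("PatternSet must be nonempty")
        bad = set(self.labels) - set(PATTERN_ORDER)
        if bad:
            raise PatternParseError(f"unknown pattern label(s): {sorted(bad)}")

    @classmethod
    def parse(cls, text: str, provenance: str = "manual") -> "PatternSet":
        """Parse a '+'-joined label string such as ``WF+TX``."""
        parts = [p.strip() for p in text.split("+")]
        if not text.strip() or any(not p for p in parts):
            raise PatternParseError(f"empty pattern label in {text!r}")
        return cls(frozenset(parts), provenance)

    def serialize(self) -> str:
        return "+".join(l for l in PATTERN_ORDER if l in self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ClassifierParams:
    """Tunable thresholds of the rule-based pattern classifier."""

    segment_s: float = 60.0        # sub-segment length
    step_s: float = 30.0           # sub-segment stride (overlapping)
    smooth_s: float = 1.0          # position smoothing before headings
    wall_band_frac: float = 0.15   # wall band, fraction of each half-extent
    wf_band_occupancy: float = 0.8
    wf_winding_turns_per_min: float = 1.5
    tx_wall_occupancy: float = 0.8
    tx_reversals_per_min: float = 2.0
    tx_winding_max: float = 0.5
    c_offwall_occupancy: float = 0.5
    c_rotation_turns_per_min: float = 2.0
    presence_frac: float = 0.2     # fraction of segments to include a label
    min_duration_min: float = 5.0


def _smooth(a: np.ndarray, n: int) -> np.ndarray:
    return uniform_filter1d(a, size=max(n, 1), mode="nearest")


def _segment_label(xc, yc, y_half, minutes, p: ClassifierParams) -> str:
    """Classify one sub-segment into a single elementary mode."""
    # wall-band membership, per axis fraction-of-half-extent
    dx = 1.0 - np.abs(xc)                  # distance to short walls / half
    dy = 1.0 - np.abs(yc) / y_half         # distance to long walls / half
    in_band = np.minimum(dx, dy) < p.wall_band_frac
    band_occ = float(np.mean(in_band))

    # net winding about the box center (square-normalized so corners count)
    phi = np.unwrap(np.arctan2(yc / y_half, xc))
    winding_rate = abs(phi[-1] - phi[0]) / (2 * np.pi) / minutes

    if band_occ > p.wf_band_occupancy and winding_rate > p.wf_winding_turns_per_min:
        return "WF"

    # single-wall occupancy: right/left (short walls) or top/bottom (long)
    walls = {
        "TY": [(xc > 1 - p.wall_band_frac), (xc < -(1 - p.wall_band_frac))],
        "TX": [(yc > y_half * (1 - p.wall_band_frac)),
               (yc < -y_half * (1 - p.wall_band_frac))],
    }
    for tlabel, bands in walls.items():
        for band in bands:
            if float(np.mean(band)) > p.tx_wall_occupancy:
                along = yc / y_half if tlabel == "TY" else xc
                if (_reversal_rate(along, minutes) >= p.tx_reversals_per_min
                        and winding_rate < p.tx_winding_max):
                    return tlabel

    # circling: sustained one-signed heading rotation away from the walls
    if 1 - band_occ > p.c_offwall_occupancy:
        vx, vy = np.diff(xc), np.diff(yc / y_half)
        ok = np.hypot(vx, vy) > 1e-9
        heading = np.arctan2(vy[ok], vx[ok])
        turn = np.angle(np.exp(1j * np.diff(heading)))
        net = abs(np.sum(turn)) / (2 * np.pi) / minutes
        total = np.sum(np.abs(turn)) / (2 * np.pi) / minutes
        if net > p.c_rotation_turns_per_min and (total == 0 or net / total > 0.5):
            return "C"
    return "R"


def _reversal_rate(coord: np.ndarray, minutes: float) -> float:
    """Debounced direction reversals per minute along one axis.

    Increments below 2% of the axis extent (pauses, jitter) are ignored
    before counting sign changes.
    """
    d = np.diff(coord)
    d = d[np.abs(d) > 0.04]        # 2% of the [-1, 1] extent
    if d.size < 2:
        return 0.0
    return float(np.sum(np.sign(d[:-1]) != np.sign(d[1:]))) / minutes


def classify_patterns(win: Trajectory, params: ClassifierParams | None = None
                      ) -> PatternSet:
    """Rule-based pattern set for one analysis window.

    The window is cut into overlapping sub-segments (60 s, 30 s stride by
    default); each segment gets one elementary label and the window's
    PatternSet is the union of labels present in more than
    ``presence_frac`` of segments (falling back to {R} if none reaches
    the bar).
    """
    p = params or ClassifierParams()
    span_min = (win.t[-1] - win.t[0]) / 60.0 if len(win) else 0.0
    if span_min < p.min_duration_min:
        from .kinematics import WindowError
        raise WindowError(
            f"window of {span_min:.2f} min shorter than the "
            f"{p.min_duration_min} min classification minimum"
        )
    fr = win.frame_rate
    n_smooth = int(round(p.smooth_s * fr))
    xs = _smooth(win.xc, n_smooth)
    ys = _smooth(win.yc, n_smooth)
    # 1 Hz decimation stabilizes headings/reversals against 30 Hz jitter
    dec = max(int(round(fr)), 1)
    xs, ys = xs[::dec], ys[::dec]

    seg_n = int(round(p.segment_s))        # samples at 1 Hz
    step_n = int(round(p.step_s))
    labels = []
    for start in range(0, xs.size - seg_n + 1, step_n):
        sl = slice(start, start + seg_n)
        labels.append(_segment_label(xs[sl], ys[sl], win.y_half_norm,
                                     p.segment_s / 60.0, p))
    if not labels:
        labels = [_segment_label(xs, ys, win.y_half_norm,
                                 xs.size / 60.0, p)]
    counts = pd.Series(labels).value_counts(normalize=True)
    present = frozenset(counts[counts > p.presence_frac].index)
    if not present:
        present = frozenset({"R"})
    return PatternSet(present, provenance="rule-based")


def pattern_change_index(before: PatternSet, after: PatternSet) -> float:
    """New-pattern fraction: |after \\ before| / |after|, in [0, 1].

    0 means every post-stimulus pattern was already expressed before; 1
    means a complete switch of repertoire.
    """
    if len(before) == 0 or len(after) == 0:
        raise ValueError("pattern sets must be nonempty")
    new = after.labels - before.labels
    return len(new) / len(after.labels)


def load_annotations(stream) -> dict[str, tuple[PatternSet, PatternSet]]:
    """Load manual before/after pattern annotations from a TSV.

    Expected columns: ``fish_id``, ``patterns_before``, ``patterns_after``
    with '+'-joined labels.
    """
    if isinstance(stream, str) and "\t" in stream:
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str)
    need = ["fish_id", "patterns_before", "patterns_after"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise PatternParseError(f"annotation file missing column(s): {missing}")
    out = {}
    for _, row in df.iterrows():
        for col in ("patterns_before", "patterns_after"):
            if pd.isna(row[col]) or not str(row[col]).strip():
                raise PatternParseError(
                    f"empty pattern cell for fish {row['fish_id']!r}")
        out[row["fish_id"]] = (PatternSet.parse(row["patterns_before"]),
                               PatternSet.parse(row["patterns_after"]))
    return out


@dataclass
class PatternTable:
    """Group x pattern-category contingency table.

    With ``combination`` granularity each fish contributes one count to
    its full '+'-joined category and row sums equal group sizes; with
    ``elementary`` granularity each expressed label is counted, so a
    multi-pattern fish is counted more than once (``multi_label`` set).
    """

    counts: pd.DataFrame
    granularity: str = "combination"
    multi_label: bool = False


def pattern_distribution(cohort: list[tuple[str, PatternSet]],
                         granularity: str = "combination") -> PatternTable:
    """Contingency counts of pattern categories per group."""
    if granularity not in {"combination", "elementary"}:
        raise ValueError(f"unknown granularity {granularity!r}")
    rows = []
    for group, ps in cohort:
        if granularity == "combination":
            rows.append((group, ps.serialize()))
        else:
            rows.extend((group, lab) for lab in PATTERN_ORDER if lab in ps)
    df = pd.DataFrame(rows, columns=["group", "category"])
    table = pd.crosstab(df["group"], df["category"])
    # stable column order: elementary order, then combinations alphabetically
    def key(c):
        return (PATTERN_ORDER.index(c) if c in PATTERN_ORDER
                else len(PATTERN_ORDER), c)
    table = table[sorted(table.columns, key=key)]
    multi = (granularity == "elementary"
             and any(len(ps) > 1 for _, ps in cohort))
    return PatternTable(counts=table, granularity=granularity,
                        multi_label=multi)
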