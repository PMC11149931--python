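"""Change indexes, the individual olfactory score, and responder calls.

Each kinematic parameter's stimulus-induced change is summarized with the
bounded signed index (after - before)/(after + before), the standard
before/after contrast of fish olfactory assays: 0 means no change, the
sign gives the direction, and |index| -> 1 as the change saturates.  The
individual olfactory score sums the absolute indexes for position, speed
and combined X+Y round trips plus the (already non-negative) pattern
change index; a fish scoring above 1.5 is called a responder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinematics import WindowKinematics
from .patterns import PatternSet, pattern_change_index

RESPONDER_THRESHOLD = 1.5


@dataclass
class ResponseIndexes:
    """The four change indexes for one fish x condition."""

    idx_position: float      # signed, in [-1, 1]; + = toward odor side
    idx_speed: float         # signed, in [-1, 1]; + = faster after
    idx_roundtrips: float    # signed, in [-1, 1]; + = more crossings after
    idx_pattern: float       # in [0, 1]; fraction of new patterns


@dataclass
class OlfactoryScore:
    """Composite score in [0, 4] and the responder call against 1.5."""

    value: float
    threshold: float = RESPONDER_THRESHOLD
    responder: bool = False


def change_index(before: float, after: float) -> float:
    """(after - before) / (after + before) for non-negative quantities.

    Defined as 0 when both are 0 (a zero-activity window shows no
    evidence of change).
    """
    if before < 0 or after < 0:
        raise ValueError(
            "change_index requires non-negative inputs; shift signed "
            "quantities first (see position_change_index)"
        )
    total = before + after
    if total == 0:
        return 0.0
    return (after - before) / total


def position_change_index(before: float, after: float) -> float:
    """Change index for mean X position, shifted off the signed scale.

    Mean Xc lives in [-1, 1] where the raw ratio is unbounded near 0, so
    both means are shifted by +1 onto [0, 2] first.  Positive iff the
    fish moved toward the odor side.
    """
    for v in (before, after):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"mean X position {v} outside [-1, 1]")
    return change_index(before + 1.0, after + 1.0)


def position_change_half_difference(before: float, after: float) -> float:
    """Alternative position contrast (after - before)/2, also in [-1, 1]."""
    for v in (before, after):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"mean X position {v} outside [-1, 1]")
    return (after - before) / 2.0


def roundtrip_change_index(kin_before: WindowKinematics,
                           kin_after: WindowKinematics) -> float:
    """Change index of the combined X+Y round-trip count."""
    return change_index(kin_before.round_trips_x + kin_before.round_trips_y,
                        kin_after.round_trips_x + kin_after.round_trips_y)


def response_indexes(kin_before: WindowKinematics,
                     kin_after: WindowKinematics,
                     patterns_before: PatternSet,
                     patterns_after: PatternSet,
                     position_mode: str = "shift") -> ResponseIndexes:
    """All four indexes from windowed kinematics plus pattern sets."""
    if position_mode == "shift":
        idx_pos = position_change_index(kin_before.mean_position_x,
                                        kin_after.mean_position_x)
    elif position_mode == "half_difference":
        idx_pos = position_change_half_difference(
            kin_before.mean_position_x, kin_after.mean_position_x)
    else:
        raise ValueError(f"unknown position_mode {position_mode!r}")
    return ResponseIndexes(
        idx_position=idx_pos,
        idx_speed=change_index(kin_before.mean_speed, kin_after.mean_speed),
        idx_roundtrips=roundtrip_change_index(kin_before, kin_after),
        idx_pattern=pattern_change_index(patterns_before, patterns_after),
    )


def olfactory_score(idx: ResponseIndexes,
                    threshold: float = RESPONDER_THRESHOLD) -> OlfactoryScore:
    """score = |position| + |speed| + |round trips X+Y| + pattern; responder iff > threshold."""
    value = (abs(idx.idx_position) + abs(idx.idx_speed)
             + abs(idx.idx_roundtrips) + idx.idx_pattern)
    return OlfactoryScore(value=value, threshold=threshold,
                          responder=value > threshold)


def cohort_response_summary(groups: dict[str, list[OlfactoryScore]]
                            ) -> dict[str, dict]:
    """Per-group responder fraction and score distribution quantiles."""
    out = {}
    for group, scores in groups.items():
        if not scores:
            raise ValueError(f"group {group!r} has no fish")
        vals = np.array([s.value for s in scores])
        out[group] = {
            "n": int(vals.size),
            "responder_frac": float(np.mean([s.responder for s in scores])),
            "score_quantiles": {
                q: float(np.quantile(vals, q / 100))
                for q in (0, 25, 50, 75, 100)
            },
        }
    return out


def pool_responder_conditions(per_condition: dict[str, dict],
                              min_frac: float = 0.4) -> list[dict]:
    """Pool per-fish records from conditions with responder fraction > min_frac.

    ``per_condition`` maps condition name to
    ``{"responder_frac": float, "records": [per-fish dicts]}``; each
    pooled record is tagged with its source condition so baseline
    personality (pattern, speed) analyses can trace provenance.  The
    threshold is strict: a condition at exactly ``min_frac`` is excluded.
    Returns an empty list (with a warning) when nothing qualifies.
    """
    pooled = []
    for cond, summ in per_condition.items():
        if summ["responder_frac"] > min_frac:
            for rec in summ["records"]:
                pooled.append({**rec, "condition": cond})
    if not pooled:
        warnings.warn(
            f"no condition exceeded the {min_frac:.0%} responder threshold; "
            "nothing pooled", stacklevel=2)
    return pooled
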