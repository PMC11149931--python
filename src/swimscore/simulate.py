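"""Agent-based simulator for larval-fish trajectories in the test box.

Generates 30 Hz tracks over 60 min in an 11.5 x 8.5 cm arena with the
statistical structure the analysis pipeline assumes: baseline personality
modes (random swim, wall following, circling, thigmotaxis along either
axis), morph-specific speed presets, and parameterized odor responses at
minute 30 — attraction toward the odor side, restriction of back-and-forth
excursions, speed change, and switching of swim mode.  Every track comes
with a per-second ground-truth ethogram so classifier and scoring tests
can assert against the generating process.

Kinematic updates per mode:

* R — persistent random walk: heading diffuses (Brownian increments),
  constant within-run speed, reflecting walls (implemented exactly by
  folding the free path into the box).
* WF — perimeter following at a fixed wall offset with a constant
  circulation direction and small arc-length noise.
* C — noisy circular orbit away from the walls.
* TX / TY — sinusoidal shuttling along one wall (long or short axis).

Odor attraction uses an Ornstein-Uhlenbeck pull of the X coordinate
toward an odor-side home position: a literal additive drift under
reflecting walls folds into oscillation and produces no net shift, while
the OU pull has the drift-equilibrium the assay expects (the fish ends up
stationed near the odor delivery point, with residual spread set by its
own step size and the pull rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .io import BoxGeometry, RawTrack, TrialDesign

MODES = ("R", "WF", "C", "TX", "TY")

PX_ORIGIN = 40.0       # pixel offset of the arena corner
PX_PER_CM = 62.0       # camera scale


class SimValidationError(ValueError):
    """A simulation spec field is invalid; the message names it."""


def default_geometry() -> BoxGeometry:
    """Box geometry matching the simulator's pixel frame."""
    return BoxGeometry(
        px_x=(PX_ORIGIN, PX_ORIGIN + PX_PER_CM * 11.5),
        px_y=(PX_ORIGIN, PX_ORIGIN + PX_PER_CM * 8.5),
    )


@dataclass
class ModeParams:
    """Per-mode kinematic parameters (cm / s units)."""

    mean_speed: float = 1.5          # cm/s; an individual trait, fixed per fish
    speed_cv: float = 0.15           # between-fish speed variability (cohorts)
    heading_noise: float = 1.5       # rad / sqrt(s), R-mode heading diffusion
    wall_offset_cm: float = 0.5      # WF path / thigmotaxis wall distance
    circle_radius_cm: float = 2.0
    osc_amplitude_frac: float = 0.8  # thigmotaxis amplitude / usable half-span
    osc_period_s: float = 12.0
    pos_noise_cm: float = 0.05       # tracking-like positional jitter
    arc_noise: float = 0.3           # WF arc-length noise, cm / sqrt(s)

    def validate(self) -> None:
        if not (0 < self.mean_speed <= 10):
            raise SimValidationError(
                f"mean_speed must be in (0, 10] cm/s, got {self.mean_speed}")
        for name in ("heading_noise", "wall_offset_cm", "circle_radius_cm",
                     "osc_period_s", "pos_noise_cm", "arc_noise", "speed_cv"):
            if getattr(self, name) < 0:
                raise SimValidationError(f"{name} must be non-negative")
        if not (0 < self.osc_amplitude_frac <= 1):
            raise SimValidationError("osc_amplitude_frac must be in (0, 1]")


@dataclass
class ModeProgram:
    """Behavior program: a fixed cycled mode sequence or a Markov chain."""

    kind: str                                    # "fixed" | "markov"
    sequence: list[tuple[str, float]] | None = None   # (mode, duration_s)
    states: list[str] | None = None
    transition: np.ndarray | None = None
    mean_dwell_s: float = 60.0

    @classmethod
    def fixed(cls, sequence) -> "ModeProgram":
        if isinstance(sequence, str):
            sequence = [(sequence, math.inf)]
        return cls(kind="fixed", sequence=list(sequence))

    @classmethod
    def markov(cls, states, transition, mean_dwell_s=60.0) -> "ModeProgram":
        return cls(kind="markov", states=list(states),
                   transition=np.asarray(transition, float),
                   mean_dwell_s=mean_dwell_s)

    def validate(self) -> None:
        if self.kind == "fixed":
            if not self.sequence:
                raise SimValidationError("fixed mode_program needs a sequence")
            for mode, dur in self.sequence:
                if mode not in MODES:
                    raise SimValidationError(f"unknown mode {mode!r}")
                if dur <= 0:
                    raise SimValidationError("mode durations must be positive")
        elif self.kind == "markov":
            if self.states is None or self.transition is None:
                raise SimValidationError("markov program needs states and matrix")
            P = self.transition
            if P.shape != (len(self.states), len(self.states)):
                raise SimValidationError("transition matrix shape mismatch")
            if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise SimValidationError("transition rows must sum to 1")
            if self.mean_dwell_s <= 0:
                raise SimValidationError("mean_dwell_s must be positive")
        else:
            raise SimValidationError(f"unknown program kind {self.kind!r}")

    def sample_seconds(self, n_seconds: int, rng: np.random.Generator
                       ) -> np.ndarray:
        """Per-second mode labels over n_seconds."""
        self.validate()
        out = np.empty(n_seconds, dtype=object)
        t = 0
        if self.kind == "fixed":
            i = 0
            while t < n_seconds:
                mode, dur = self.sequence[i % len(self.sequence)]
                span = n_seconds - t if math.isinf(dur) else int(round(dur))
                out[t:t + span] = mode
                t += max(span, 1)
                i += 1
            return out
        idx = {s: i for i, s in enumerate(self.states)}
        state = self.states[rng.integers(len(self.states))]
        while t < n_seconds:
            dwell = int(np.clip(rng.exponential(self.mean_dwell_s), 5, 600))
            out[t:t + dwell] = state
            t += dwell
            state = self.states[rng.choice(len(self.states),
                                           p=self.transition[idx[state]])]
        return out


@dataclass
class OdorResponse:
    """Parameterized response to the minute-30 odor injection.

    ``attraction_rate_per_s`` is the relaxation rate of the OU pull of X
    toward the odor-side home position (in normalized box units per
    second of displacement from target; 0 disables attraction).
    ``crossing_amplitude_multiplier`` scales the spatial excursions of
    the responsive modes (X steps of random swim, oscillation amplitude
    of thigmotaxis, orbit radius of circling), emulating the observed
    restriction of activity and reduction of back-and-forth crossings.
    """

    onset_min: float = 30.0
    latency_s: float = 30.0
    attraction_rate_per_s: float = 0.0
    speed_multiplier: float = 1.0
    crossing_amplitude_multiplier: float = 1.0
    post_mode_program: ModeProgram | None = None
    home_frac: float = 0.85       # odor-side home position, fraction of length

    def validate(self) -> None:
        for name in ("onset_min", "latency_s", "attraction_rate_per_s"):
            if getattr(self, name) < 0:
                raise SimValidationError(f"{name} must be non-negative")
        for name in ("speed_multiplier", "crossing_amplitude_multiplier"):
            if getattr(self, name) <= 0:
                raise SimValidationError(f"{name} must be positive")
        if self.post_mode_program is not None:
            self.post_mode_program.validate()

    @property
    def active(self) -> bool:
        return (self.attraction_rate_per_s > 0
                or self.speed_multiplier != 1.0
                or self.crossing_amplitude_multiplier != 1.0
                or self.post_mode_program is not None)


@dataclass
class SimSpec:
    """Full specification of one simulated fish."""

    fish_id: str = "sim"
    duration_min: float = 60.0
    frame_rate: float = 30.0
    box: BoxGeometry = field(default_factory=default_geometry)
    mode_program: ModeProgram = field(
        default_factory=lambda: ModeProgram.fixed("R"))
    mode_params: ModeParams = field(default_factory=ModeParams)
    odor_response: OdorResponse = field(default_factory=OdorResponse)
    odor_side: str = "right"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_min <= 0:
            raise SimValidationError("duration_min must be positive")
        if self.frame_rate <= 0:
            raise SimValidationError("frame_rate must be positive")
        if self.odor_side not in {"left", "right"}:
            raise SimValidationError(f"odor_side must be left/right")
        self.mode_program.validate()
        self.mode_params.validate()
        self.odor_response.validate()


@dataclass
class GroundTruth:
    """Generating process of one simulated track."""

    mode_per_second: np.ndarray        # dtype=object labels
    response_active_from_s: float | None
    draws: dict


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded path into [lo, hi] (exact reflecting walls)."""
    span = hi - lo
    m = np.mod(u - lo, 2 * span)
    return lo + np.where(m > span, 2 * span - m, m)


def _gen_random(n, dt, v, x0, y0, L, W, rng, p: ModeParams,
                responsive, resp: OdorResponse, odor_right):
    theta = rng.uniform(0, 2 * np.pi) + np.cumsum(
        p.heading_noise * math.sqrt(dt) * rng.standard_normal(n))
    m = resp.crossing_amplitude_multiplier if responsive else 1.0
    step_x = m * v * dt * np.cos(theta)
    step_y = v * dt * np.sin(theta)
    y = _fold(y0 + np.cumsum(step_y), 0.0, W)
    kappa = resp.attraction_rate_per_s if responsive else 0.0
    if kappa > 0:
        target = resp.home_frac * L if odor_right else (1 - resp.home_frac) * L
        a = kappa * dt
        u = step_x + a * target
        x = lfilter([1.0], [1.0, -(1.0 - a)], u, zi=[(1.0 - a) * x0])[0]
        x = np.clip(x, 0.0, L)
    else:
        x = _fold(x0 + np.cumsum(step_x), 0.0, L)
    return x, y


def _gen_wall_follow(n, dt, v, x0, y0, L, W, rng, p: ModeParams, direction):
    d = p.wall_offset_cm
    a_len, b_len = L - 2 * d, W - 2 * d
    per = 2 * (a_len + b_len)
    # project the start point onto the perimeter path
    cand = [
        (abs(y0 - d), np.clip(x0 - d, 0, a_len)),                    # bottom
        (abs(x0 - (L - d)), a_len + np.clip(y0 - d, 0, b_len)),      # right
        (abs(y0 - (W - d)), a_len + b_len + np.clip(L - d - x0, 0, a_len)),
        (abs(x0 - d), 2 * a_len + b_len + np.clip(W - d - y0, 0, b_len)),
    ]
    s0 = min(cand)[1]
    t = np.arange(1, n + 1) * dt
    s = s0 + direction * (v * t + np.cumsum(
        p.arc_noise * math.sqrt(dt) * rng.standard_normal(n)))
    s = np.mod(s, per)
    x = np.empty(n)
    y = np.empty(n)
    seg1, seg2 = s < a_len, (s >= a_len) & (s < a_len + b_len)
    seg3 = (s >= a_len + b_len) & (s < 2 * a_len + b_len)
    seg4 = s >= 2 * a_len + b_len
    x[seg1], y[seg1] = d + s[seg1], d
    x[seg2], y[seg2] = L - d, d + (s[seg2] - a_len)
    x[seg3], y[seg3] = L - d - (s[seg3] - a_len - b_len), W - d
    x[seg4], y[seg4] = d, W - d - (s[seg4] - 2 * a_len - b_len)
    return x, y


def _gen_circle(n, dt, v, x0, y0, L, W, rng, p: ModeParams, direction,
                responsive, resp: OdorResponse, odor_right):
    r = p.circle_radius_cm
    if responsive:
        r *= resp.crossing_amplitude_multiplier
    margin = r + 0.3
    theta0 = rng.uniform(0, 2 * np.pi)
    cx, cy = x0 - r * math.cos(theta0), y0 - r * math.sin(theta0)
    if responsive and resp.attraction_rate_per_s > 0:
        # station the orbit at the odor delivery point (mid-height of
        # the odor-side short wall)
        cx = resp.home_frac * L if odor_right else (1 - resp.home_frac) * L
        cy = W / 2
    cx = float(np.clip(cx, margin, L - margin))
    cy = float(np.clip(cy, margin, W - margin))
    omega = direction * v / r
    t = np.arange(1, n + 1) * dt
    theta = theta0 + omega * t + np.cumsum(
        0.1 * math.sqrt(dt) * rng.standard_normal(n))
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def _gen_thigmotaxis(n, dt, v, x0, y0, L, W, rng, p: ModeParams, axis,
                     responsive, resp: OdorResponse, odor_right):
    d = p.wall_offset_cm
    m = resp.crossing_amplitude_multiplier if responsive else 1.0
    two_pi = 2 * np.pi
    t = np.arange(1, n + 1) * dt
    if axis == "X":                      # shuttle along a long wall
        wall = d if abs(y0 - 0) < abs(y0 - W) else W - d
        amp = m * p.osc_amplitude_frac * (L / 2 - d)
        cx = L / 2
        if responsive and resp.attraction_rate_per_s > 0:
            tgt = resp.home_frac * L if odor_right else (1 - resp.home_frac) * L
            cx = float(np.clip(tgt, amp + d, L - amp - d))
        phi = math.asin(float(np.clip((x0 - cx) / max(amp, 1e-9), -1, 1)))
        x = cx + amp * np.sin(two_pi * t / p.osc_period_s + phi)
        y = np.full(n, wall)
    else:                                # shuttle along a short wall
        wall = d if abs(x0 - 0) < abs(x0 - L) else L - d
        if responsive and resp.attraction_rate_per_s > 0:
            wall = L - d if odor_right else d
        amp = m * p.osc_amplitude_frac * (W / 2 - d)
        phi = math.asin(float(np.clip((y0 - W / 2) / max(amp, 1e-9), -1, 1)))
        x = np.full(n, wall)
        y = W / 2 + amp * np.sin(two_pi * t / p.osc_period_s + phi)
    return x, y


def simulate_trajectory(spec: SimSpec) -> tuple[RawTrack, GroundTruth]:
    """Simulate one fish; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.box.length_cm
    W = spec.box.width_cm
    fr = spec.frame_rate
    dt = 1.0 / fr
    n = int(round(spec.duration_min * 60 * fr))
    n_seconds = int(math.ceil(spec.duration_min * 60))
    resp = spec.odor_response
    odor_right = spec.odor_side == "right"

    modes_s = spec.mode_program.sample_seconds(n_seconds, rng)
    t_resp = None
    if resp.active:
        t_resp = resp.onset_min * 60 + resp.latency_s
        if resp.post_mode_program is not None and t_resp < n_seconds:
            post = resp.post_mode_program.sample_seconds(
                n_seconds - int(t_resp), rng)
            modes_s[int(t_resp):] = post

    modes_f = np.repeat(modes_s, int(round(fr)))[:n]
    responsive_f = (np.arange(n) * dt >= t_resp) if t_resp is not None \
        else np.zeros(n, bool)

    # contiguous runs of (mode, responsive) define generation segments
    change = np.flatnonzero(
        (modes_f[1:] != modes_f[:-1]) | (responsive_f[1:] != responsive_f[:-1]))
    starts = np.concatenate([[0], change + 1, [n]])

    p = spec.mode_params
    base_speed = p.mean_speed       # per-fish trait, drawn by baseline_spec
    wf_dir = 1 if rng.random() < 0.5 else -1
    c_dir = 1 if rng.random() < 0.5 else -1

    x = np.empty(n)
    y = np.empty(n)
    x0 = rng.uniform(0.15 * L, 0.85 * L)
    y0 = rng.uniform(0.15 * W, 0.85 * W)
    for i in range(starts.size - 1):
        lo, hi = int(starts[i]), int(starts[i + 1])
        if hi <= lo:
            continue
        mode = modes_f[lo]
        responsive = bool(responsive_f[lo])
        v = base_speed * (resp.speed_multiplier if responsive else 1.0)
        n_run = hi - lo
        if mode == "R":
            xr, yr = _gen_random(n_run, dt, v, x0, y0, L, W, rng, p,
                                 responsive, resp, odor_right)
        elif mode == "WF":
            xr, yr = _gen_wall_follow(n_run, dt, v, x0, y0, L, W, rng, p,
                                      wf_dir)
        elif mode == "C":
            xr, yr = _gen_circle(n_run, dt, v, x0, y0, L, W, rng, p, c_dir,
                                 responsive, resp, odor_right)
        else:
            xr, yr = _gen_thigmotaxis(n_run, dt, v, x0, y0, L, W, rng, p,
                                      "X" if mode == "TX" else "Y",
                                      responsive, resp, odor_right)
        x[lo:hi], y[lo:hi] = xr, yr
        x0, y0 = float(xr[-1]), float(yr[-1])

    if p.pos_noise_cm > 0:
        x = x + rng.normal(0, p.pos_noise_cm, n)
        y = y + rng.normal(0, p.pos_noise_cm, n)
    eps = 1e-3
    x = np.clip(x, eps, L - eps)
    y = np.clip(y, eps, W - eps)

    t = np.arange(n) * dt
    raw = RawTrack(
        fish_id=spec.fish_id, t=t,
        x_px=PX_ORIGIN + PX_PER_CM * x, y_px=PX_ORIGIN + PX_PER_CM * y,
        x_cm=x, y_cm=y, frame_rate=fr,
    )
    truth = GroundTruth(
        mode_per_second=modes_s,
        response_active_from_s=t_resp,
        draws={"base_speed": base_speed, "wf_direction": wf_dir,
               "circle_direction": c_dir, "seed": spec.seed},
    )
    return raw, truth


# ----------------------------------------------------------- presets

#: Baseline mode probabilities per morphotype: three quarters of
#: well-habituated surface fish swim randomly, while most cavefish
#: wall-follow and hybrids sit in between.  Circling is treated as a
#: post-stimulus mode, not a baseline draw.
MORPH_BASELINE_PROBS = {
    "SF": {"R": 0.75, "WF": 0.10, "TX": 0.10, "TY": 0.05},
    "CF": {"WF": 0.70, "R": 0.15, "TX": 0.10, "TY": 0.05},
    "F2": {"R": 0.40, "WF": 0.40, "TX": 0.15, "TY": 0.05},
}

#: Morph-specific mean swim speeds (cm/s).  Blind cavefish show the
#: well-documented hyperlocomotion relative to surface fish.
MORPH_SPEEDS = {"SF": 1.4, "CF": 1.6, "F2": 1.5}


def attraction_response() -> OdorResponse:
    """Strong-attraction response preset: the fish stations itself near
    the odor delivery point, speeds up, restricts X excursions, and
    switches its swim mode to odor-side circling."""
    return OdorResponse(
        attraction_rate_per_s=0.05,
        speed_multiplier=1.5,
        crossing_amplitude_multiplier=0.4,
        post_mode_program=ModeProgram.fixed("C"),
    )


def null_response() -> OdorResponse:
    """Null response: injection has no behavioral effect."""
    return OdorResponse()


def baseline_spec(morph: str = "SF", fish_id: str = "sim", seed: int = 0,
                  rng: np.random.Generator | None = None,
                  response: OdorResponse | None = None) -> SimSpec:
    """SimSpec with a morph-preset baseline mode and individual speed.

    Baseline mode and swim speed are per-fish personality draws from the
    morph's distributions, fixed for the whole track (and across days:
    :func:`personality_stability_fixture` keeps the spec and only
    refreshes the noise).  Speed draws are clipped to +/-2.5 cohort
    standard deviations.
    """
    if morph not in MORPH_BASELINE_PROBS:
        raise SimValidationError(f"unknown morph {morph!r}")
    rng = rng or np.random.default_rng(seed)
    probs = MORPH_BASELINE_PROBS[morph]
    mode = rng.choice(list(probs), p=list(probs.values()))
    params = ModeParams(mean_speed=MORPH_SPEEDS[morph])
    sd = params.speed_cv * params.mean_speed
    speed = float(np.clip(rng.normal(params.mean_speed, sd),
                          params.mean_speed - 2.5 * sd,
                          params.mean_speed + 2.5 * sd))
    params.mean_speed = speed
    return SimSpec(
        fish_id=fish_id,
        mode_program=ModeProgram.fixed(str(mode)),
        mode_params=params,
        odor_response=response or null_response(),
        seed=seed,
    )


def simulate_cohort(n_per_group: int, group_specs: dict, seed: int = 0
                    ) -> list[tuple[RawTrack, TrialDesign, GroundTruth]]:
    """Simulate cohorts of independent fish.

    ``group_specs`` maps a group label to a dict with keys ``morph``,
    optional ``response`` (OdorResponse), ``odor``, ``conc`` and ``day``.
    Per-fish seeds and personalities (baseline mode, individual speed)
    derive from ``seed``; the odor side alternates with the simulated
    day, as in the multi-day assay design.
    """
    if n_per_group < 0:
        raise SimValidationError("n_per_group must be >= 0")
    master = np.random.default_rng(seed)
    out = []
    for group, gs in group_specs.items():
        morph = gs.get("morph", "SF")
        day = int(gs.get("day", 1))
        odor_side = "right" if day % 2 == 1 else "left"
        for i in range(n_per_group):
            fish_seed = int(master.integers(2 ** 31))
            fid = f"{group}_{i:03d}"
            spec = baseline_spec(
                morph=morph, fish_id=fid, seed=fish_seed,
                response=gs.get("response"))
            spec = replace(spec, odor_side=odor_side)
            raw, truth = simulate_trajectory(spec)
            trial = TrialDesign(
                fish_id=fid, morph=morph, odor=gs.get("odor", "water"),
                syringe_concentration=float(gs.get("conc", 0.0)),
                odor_side=odor_side, day=day,
            )
            out.append((raw, trial, truth))
    return out


def personality_stability_fixture(fish_spec: SimSpec, n_days: int = 4
                                  ) -> list[RawTrack]:
    """Same fish, same mode program, fresh noise on each simulated day.

    Used to test that the classified pattern set is stable across days,
    as baseline personalities are in the assay.
    """
    fish_spec.validate()
    tracks = []
    for day in range(n_days):
        spec = replace(
            fish_spec,
            seed=int(fish_spec.seed + 10_000 * (day + 1)),
            odor_side="right" if day % 2 == 0 else "left",
        )
        raw, _ = simulate_trajectory(spec)
        tracks.append(raw)
    return tracks
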