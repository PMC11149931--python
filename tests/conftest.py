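"""Shared fixtures: geometry, trials, and synthetic trajectory builders."""

import numpy as np
import pytest

from swimscore import BoxGeometry, TrialDesign, Trajectory, default_geometry


@pytest.fixture
def geom() -> BoxGeometry:
    return default_geometry()


@pytest.fixture
def trial() -> TrialDesign:
    return TrialDesign(fish_id="f01", morph="CF", odor="alanine",
                       syringe_concentration=1e-2, odor_side="right")


def build_trajectory(t, xc, yc=None, x_cm=None, y_cm=None, frame_rate=30.0,
                     y_half_norm=0.74) -> Trajectory:
    """Trajectory from raw arrays; cm coordinates default to the affine
    image of the normalized ones in the 11.5 x 8.5 cm box."""
    t = np.asarray(t, float)
    xc = np.asarray(xc, float)
    yc = np.zeros_like(xc) if yc is None else np.asarray(yc, float)
    if x_cm is None:
        x_cm = (xc + 1.0) * 11.5 / 2.0
    if y_cm is None:
        y_cm = (yc / y_half_norm + 1.0) * 8.5 / 2.0
    return Trajectory(fish_id="t", t=t, xc=xc, yc=yc,
                      x_cm=np.asarray(x_cm, float),
                      y_cm=np.asarray(y_cm, float),
                      frame_rate=frame_rate, y_half_norm=y_half_norm)


@pytest.fixture
def make_traj():
    return build_trajectory
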