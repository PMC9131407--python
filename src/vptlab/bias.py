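"""Vector-projection bias statistics.

Each participant x condition orientation profile (8 per-orientation means) is
projected onto two orthogonal contrasts:

* towards/away bias — mean of ``value(theta) * (-cos theta)``; positive when
  responses slow as the character faces away from the participant (the mental
  rotation effect);
* left/right bias — mean of ``value(theta) * (-sin theta)``; positive when
  left-facing characters (45/90/135 deg) are judged faster, i.e. when the
  profile tilts towards the viewpoint of a person seated on the left.

The sign of the left/right bias follows the study's results convention
(positive = faster for left-facing items, hence more positive with a person on
the left); the two possible conventions differ only by a global sign.

For a profile linear in the disparity to a viewpoint, each projection returns
the slope times the projection gain (1/8) * sum d(theta) * (-cos theta) =
38.40990..., identical for the self and the 90/270-deg other viewpoints; the
left/right bias of a person-present profile isolates the other-viewpoint slope
the same way.  The perspective-taking score is the left/right bias with the
person on the left minus with the person on the right.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ORIENTATIONS, other_disparities, self_disparities

_THETA = np.radians(np.array(ORIENTATIONS, dtype=float))

#: Projection gain: bias produced by a unit (1 ms/deg) linear disparity slope.
PROJECTION_GAIN: float = float(np.mean(self_disparities() * -np.cos(_THETA)))


def towards_away_bias(values) -> float | np.ndarray:
    """Cosine projection of an 8-orientation profile (ms, or proportion for
    error profiles).  ``values`` is ordered by ORIENTATIONS; the projection is
    applied along the last axis."""
    values = np.asarray(values, dtype=float)
    return values @ (-np.cos(_THETA)) / len(ORIENTATIONS)


def left_right_bias(values) -> float | np.ndarray:
    """Sine projection of an 8-orientation profile; positive = faster for
    left-facing orientations."""
    values = np.asarray(values, dtype=float)
    return values @ (-np.sin(_THETA)) / len(ORIENTATIONS)


def perspective_taking_score(lr_left: float, lr_right: float) -> float:
    """Left/right bias with the person on the left minus on the right;
    positive = spontaneous adoption of the other's viewpoint."""
    if lr_left is None or lr_right is None or np.isnan(lr_left) or np.isnan(lr_right):
        return float("nan")
    return lr_left - lr_right


def bias_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Both biases for every complete profile row.

    Input is the wide profile table from
    :func:`vptlab.preprocess.orientation_profiles`; incomplete profiles get
    NaN biases.  Units follow the profile measure (ms or proportion).
    """
    vals = profiles[list(ORIENTATIONS)].to_numpy(dtype=float)
    out = profiles[["participant_id", "movement", "person_location", "measure"]].copy()
    ta = towards_away_bias(vals)
    lr = left_right_bias(vals)
    incomplete = ~profiles.complete.to_numpy()
    ta = np.where(incomplete, np.nan, ta)
    lr = np.where(incomplete, np.nan, lr)
    out["ta_bias"] = ta
    out["lr_bias"] = lr
    return out


def perspective_scores(biases: pd.DataFrame, movement: str = "pooled") -> pd.DataFrame:
    """Per-participant perspective-taking score (ms) at the given movement
    scope: lr_bias(person-left) - lr_bias(person-right)."""
    sub = biases[(biases.movement == movement) & (biases.measure == "rt_ms")]
    wide = sub.pivot(index="participant_id", columns="person_location", values="lr_bias")
    missing = [c for c in ("left", "right") if c not in wide.columns]
    if missing:
        raise ValueError(f"missing person locations {missing} in bias table")
    out = pd.DataFrame({
        "participant_id": wide.index,
        "pt_score": (wide["left"] - wide["right"]).to_numpy(),
    }).reset_index(drop=True)
    return out


def error_rate_biases(profiles: pd.DataFrame) -> pd.DataFrame:
    """Bias table for error-rate profiles (identical projections, units are
    proportions)."""
    if not (profiles.measure == "error_rate").all():
        raise ValueError("error_rate_biases expects error-rate profiles")
    return bias_table(profiles)


def _check_orthogonality() -> None:
    """The self- and other-disparity contrasts are exactly orthogonal to the
    opposite projection; used as an internal consistency assertion."""
    assert abs(towards_away_bias(other_disparities("left"))) < 1e-12
    assert abs(left_right_bias(self_disparities())) < 1e-12
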