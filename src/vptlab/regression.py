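"""Per-participant mental-rotation regressions.

Two fits per participant, both ordinary least squares on condition-cell mean
RTs with disparities in degrees (so coefficients are in ms/degree):

* simple self-rotation fit — RT on the disparity to the participant, over all
  location x orientation cells in scope;
* dual-viewpoint fit — RT on the disparity to the participant *and* to the
  other person, over the 16 person-present cells (8 orientations x
  person-left/right).  The two predictors are exactly orthogonal over those
  cells, so each coefficient equals its simple-regression counterpart.

Scopes: 'all' (cells pooled over movement), 'free', 'restricted'.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .design import ORIENTATIONS, other_disparities, self_disparities

logger = logging.getLogger(__name__)

SCOPES = ("all", "free", "restricted")


@dataclasses.dataclass
class RotationFit:
    """OLS coefficients of one participant's rotation regression."""

    participant_id: str
    scope: str
    intercept: float
    beta_self: float
    beta_other: float | None
    r_squared: float


def _cells_for_scope(profiles: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    movement = "pooled" if scope == "all" else scope
    return profiles[(profiles.movement == movement) & (profiles.measure == "rt_ms")]


def _ols(X: np.ndarray, y: np.ndarray):
    X1 = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        return None
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / tss if tss > 0 else np.nan
    return coef, r2


def fit_self_rotation(profiles: pd.DataFrame, participant_id: str,
                      scope: str = "all") -> RotationFit | None:
    """Simple regression of cell-mean RT on the disparity to the participant,
    over every complete location x orientation cell in scope."""
    sub = _cells_for_scope(profiles, scope)
    sub = sub[(sub.participant_id == participant_id) & sub.complete]
    if sub.empty:
        logger.info("no complete profiles for %s in scope %s", participant_id, scope)
        return None
    d_self = self_disparities()
    y = sub[list(ORIENTATIONS)].to_numpy(dtype=float).ravel()
    X = np.tile(d_self, len(sub))[:, None]
    if len(np.unique(X)) < 3:
        return None
    fit = _ols(X, y)
    if fit is None:
        logger.warning("rank-deficient self-rotation design for %s", participant_id)
        return None
    coef, r2 = fit
    return RotationFit(participant_id, scope, coef[0], coef[1], None, r2)


def fit_dual_viewpoint(profiles: pd.DataFrame, participant_id: str,
                       scope: str = "all") -> RotationFit | None:
    """Dual regression of the 16 person-present cell means on the disparities
    to the participant and to the other person."""
    sub = _cells_for_scope(profiles, scope)
    sub = sub[(sub.participant_id == participant_id)
              & sub.person_location.isin(["left", "right"])]
    if len(sub) != 2 or not sub.complete.all():
        logger.info("incomplete 16-cell design for %s in scope %s", participant_id, scope)
        return None
    sub = sub.set_index("person_location")
    d_self = self_disparities()
    rows_y, rows_x = [], []
    for loc in ("left", "right"):
        rows_y.append(sub.loc[loc, list(ORIENTATIONS)].to_numpy(dtype=float))
        rows_x.append(np.column_stack([d_self, other_disparities(loc)]))
    y = np.concatenate(rows_y)
    X = np.vstack(rows_x)
    fit = _ols(X, y)
    if fit is None:
        logger.warning("rank-deficient dual-viewpoint design for %s", participant_id)
        return None
    coef, r2 = fit
    return RotationFit(participant_id, scope, coef[0], coef[1], coef[2], r2)


def fit_cohort(profiles: pd.DataFrame, kind: str = "dual",
               scope: str = "all") -> pd.DataFrame:
    """Fit every participant; returns one row per successful fit."""
    fitter = {"dual": fit_dual_viewpoint, "self": fit_self_rotation}[kind]
    rows = []
    for pid in profiles.participant_id.unique():
        fit = fitter(profiles, pid, scope=scope)
        if fit is not None:
            rows.append(dataclasses.asdict(fit))
    return pd.DataFrame(rows)


def summarise_fits(fits: pd.DataFrame, coefficient: str = "beta_self") -> dict:
    """Group summary of one coefficient: mean, SD, one-sample t against zero,
    Cohen's d, JZS BF10, and the count of positive slopes."""
    from .inference import jzs_bf_ttest, one_sample_t

    values = fits[coefficient].dropna().to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two fits to summarise")
    out = {
        "coefficient": coefficient,
        "n": len(values),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "n_positive": int((values > 0).sum()),
    }
    if out["sd"] == 0:
        out.update(degenerate=True, t=np.nan, df=len(values) - 1,
                   p=np.nan, d=np.nan, bf10=np.nan)
        logger.warning("all %s fits identical; t-test undefined", coefficient)
        return out
    test = one_sample_t(values)
    out.update(degenerate=False, t=test.statistic, df=test.df, p=test.p,
               d=test.effect_size, bf10=jzs_bf_ttest(test.statistic, len(values)))
    return out
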