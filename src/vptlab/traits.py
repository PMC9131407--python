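"""Questionnaire scoring and individual-differences analyses.

Scoring rules:

* AQ — 50 items answered on a 4-point agreement scale (0 = definitely agree
  ... 3 = definitely disagree); an item scores 1 when the response falls on
  the autistic-trait side (agree for agree-keyed items, disagree otherwise);
  total 0-50.
* IRI — 28 items on a 0-4 scale, reverse-keyed items scored 4 - response;
  four 7-item subscales (perspective taking, empathic concern, fantasy,
  personal distress), total 0-112.
* STQ-STA — 37 yes/no items, total = number of yes responses.

The default keys ship with the package so the pipeline runs end-to-end; they
are synthetic stand-ins with the published keys' *structure* (26 agree-keyed
AQ items; 9 reverse-keyed IRI items; subscale membership by position), not the
copyrighted item texts.  Pass the published keys to score real data.

The analyses correlate each participant's spontaneous perspective-taking
score with age and the three trait totals, and enter them hierarchically
(age, STQ, AQ, IRI) into a nested OLS with R-squared-change F-tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .inference import TestResult, jeffreys_bf_correlation, pearson_r

AQ_N_ITEMS = 50
IRI_N_ITEMS = 28
STQ_N_ITEMS = 37

# Synthetic stand-in keys (structure matches the published instruments).
#: AQ items scored in the agree direction (1-based indices; 26 items).
DEFAULT_AQ_AGREE_KEYED: frozenset[int] = frozenset(
    list(range(1, 27)))
#: IRI reverse-keyed items (1-based indices; 9 items).
DEFAULT_IRI_REVERSED: frozenset[int] = frozenset({3, 4, 7, 12, 13, 14, 15, 18, 19})
#: IRI subscale membership: 7 consecutive items per subscale (synthetic order).
DEFAULT_IRI_SUBSCALES: dict[str, tuple[int, ...]] = {
    "iri_pt": tuple(range(1, 8)),
    "iri_ec": tuple(range(8, 15)),
    "iri_fs": tuple(range(15, 22)),
    "iri_pd": tuple(range(22, 29)),
}

HIERARCHY = ("age", "stq_sta", "aq_total", "iri_total")


def _check_items(items, n, lo, hi, label):
    items = np.asarray(items)
    if items.shape[-1] != n:
        raise ValueError(f"{label} expects {n} items, got {items.shape[-1]}")
    missing = np.flatnonzero(pd.isna(items))
    if len(missing):
        raise ValueError(f"{label}: missing responses at items {missing.tolist()}")
    items = items.astype(int)
    if items.min() < lo or items.max() > hi:
        raise ValueError(f"{label}: responses must lie in [{lo}, {hi}]")
    return items


def score_aq(items, agree_keyed=DEFAULT_AQ_AGREE_KEYED) -> int:
    """AQ total: 1 point per item answered on the autistic-trait side.

    ``items``: 50 responses, 0 = definitely agree, 1 = slightly agree,
    2 = slightly disagree, 3 = definitely disagree.
    """
    items = _check_items(items, AQ_N_ITEMS, 0, 3, "AQ")
    agree = items <= 1
    keyed = np.array([i + 1 in agree_keyed for i in range(AQ_N_ITEMS)])
    return int(np.sum(agree == keyed))


def score_iri(items, reversed_items=DEFAULT_IRI_REVERSED,
              subscales=DEFAULT_IRI_SUBSCALES) -> dict[str, int]:
    """IRI total and subscales with 0-4 scoring and reversal."""
    items = _check_items(items, IRI_N_ITEMS, 0, 4, "IRI")
    rev = np.array([i + 1 in reversed_items for i in range(IRI_N_ITEMS)])
    scored = np.where(rev, 4 - items, items)
    out = {name: int(scored[[i - 1 for i in idx]].sum())
           for name, idx in subscales.items()}
    out["iri_total"] = int(scored.sum())
    assert out["iri_total"] == sum(out[k] for k in subscales)
    return out


def score_stq(items) -> int:
    """STQ-STA total: count of yes (1) responses over the 37 STA items."""
    items = _check_items(items, STQ_N_ITEMS, 0, 1, "STQ")
    return int(items.sum())


# ---------------------------------------------------------------------------
# item-level generation (so the scoring functions are exercised end to end)

def aq_items_from_total(total: int, rng: np.random.Generator,
                        agree_keyed=DEFAULT_AQ_AGREE_KEYED) -> np.ndarray:
    """Item responses whose AQ score equals ``total`` (keyed items chosen at
    random; slight/definite strength random)."""
    if not 0 <= total <= AQ_N_ITEMS:
        raise ValueError("AQ total out of range")
    scored = np.zeros(AQ_N_ITEMS, bool)
    scored[rng.choice(AQ_N_ITEMS, size=total, replace=False)] = True
    keyed = np.array([i + 1 in agree_keyed for i in range(AQ_N_ITEMS)])
    agree = scored == keyed
    strength = rng.integers(0, 2, AQ_N_ITEMS)  # definitely/slightly
    return np.where(agree, strength, 3 - strength)


def iri_items_from_totals(subscale_totals: dict[str, int], rng: np.random.Generator,
                          reversed_items=DEFAULT_IRI_REVERSED,
                          subscales=DEFAULT_IRI_SUBSCALES) -> np.ndarray:
    """Item responses reproducing the given subscale totals after reversal."""
    scored = np.zeros(IRI_N_ITEMS, int)
    for name, idx in subscales.items():
        t = int(subscale_totals[name])
        if not 0 <= t <= 4 * len(idx):
            raise ValueError(f"{name} total out of range")
        # spread the total over the subscale's items, 0-4 each
        alloc = np.full(len(idx), t // len(idx))
        rem = t - alloc.sum()
        bump = rng.choice(len(idx), size=rem, replace=False) if rem else []
        alloc[bump] += 1
        scored[[i - 1 for i in idx]] = alloc
    rev = np.array([i + 1 in reversed_items for i in range(IRI_N_ITEMS)])
    return np.where(rev, 4 - scored, scored)


def stq_items_from_total(total: int, rng: np.random.Generator) -> np.ndarray:
    if not 0 <= total <= STQ_N_ITEMS:
        raise ValueError("STQ total out of range")
    items = np.zeros(STQ_N_ITEMS, int)
    items[rng.choice(STQ_N_ITEMS, size=total, replace=False)] = 1
    return items


# ---------------------------------------------------------------------------
# analyses

def trait_correlations(pt_scores: pd.DataFrame, questionnaires: pd.DataFrame,
                       predictors=HIERARCHY) -> pd.DataFrame:
    """Pearson r (+ p, Jeffreys BF10) of the perspective-taking score with
    each predictor, over complete cases per predictor."""
    merged = pt_scores.merge(questionnaires, on="participant_id", how="inner")
    rows = []
    for pred in predictors:
        sub = merged[["pt_score", pred]].dropna()
        if len(sub) < 4 or sub[pred].std() == 0 or sub.pt_score.std() == 0:
            rows.append(dict(predictor=pred, n=len(sub), r=np.nan, t=np.nan,
                             p=np.nan, bf10=np.nan))
            continue
        res = pearson_r(sub[pred], sub.pt_score, name=f"pt ~ {pred}")
        rows.append(dict(predictor=pred, n=res.extra["n"], r=res.statistic,
                         t=res.extra["t"], p=res.p,
                         bf10=jeffreys_bf_correlation(res.statistic, res.extra["n"])))
    return pd.DataFrame(rows)


@dataclasses.dataclass
class HierarchicalStep:
    predictors: tuple[str, ...]
    r_squared: float
    delta_r_squared: float
    f_change: float
    df: tuple[int, int]
    p_change: float


def hierarchical_regression(pt_scores: pd.DataFrame, questionnaires: pd.DataFrame,
                            blocks=tuple((p,) for p in HIERARCHY)):
    """Nested OLS of the perspective-taking score on hierarchically entered
    predictor blocks.

    Returns ``(steps, full_model)``: per step R-squared, its change, and the
    R-squared-change F-test F = dRsq * (n - k_full - 1) / ((1 - Rsq_step) * dk);
    plus the full model's standardised betas with t-tests.
    """
    import statsmodels.api as sm

    all_preds = [p for block in blocks for p in block]
    if len(set(all_preds)) != len(all_preds):
        raise ValueError("duplicate predictors across blocks")
    data = pt_scores.merge(questionnaires, on="participant_id")[
        ["pt_score"] + all_preds].dropna()
    n = len(data)
    if n <= len(all_preds) + 1:
        raise ValueError(f"too few complete cases (n={n}) for {len(all_preds)} predictors")
    degenerate = [c for c in data.columns if data[c].std(ddof=1) == 0]
    if degenerate:
        raise ValueError(f"degenerate (constant) variables: {degenerate}")
    z = (data - data.mean()) / data.std(ddof=1)
    y = z.pt_score.to_numpy()

    steps, entered = [], []
    prev_r2 = 0.0
    for block in blocks:
        entered = entered + list(block)
        X = sm.add_constant(z[entered].to_numpy())
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear predictors in block {block}")
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
        dk = len(block)
        df2 = n - len(entered) - 1
        d_r2 = r2 - prev_r2
        f_change = d_r2 * df2 / ((1 - r2) * dk) if r2 < 1 else np.inf
        from scipy.stats import f as fdist
        p_change = float(fdist.sf(f_change, dk, df2))
        steps.append(HierarchicalStep(tuple(entered), r2, d_r2, f_change,
                                      (dk, df2), p_change))
        prev_r2 = r2

    full = sm.OLS(y, sm.add_constant(z[all_preds].to_numpy())).fit()
    full_model = pd.DataFrame({
        "predictor": all_preds,
        "beta_std": full.params[1:],
        "t": full.tvalues[1:],
        "p": full.pvalues[1:],
    })
    return steps, full_model
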