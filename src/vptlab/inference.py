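"""Within-subject inferential machinery.

t-tests, repeated-measures ANOVA (delegated to pingouin, with partial eta
squared recomputed from F and the dfs), default-prior Bayes factors computed
by numerical quadrature, Pearson correlations, and power calculations by
noncentral-t inversion.

Bayes factors follow the defaults of the JASP software family: the one-sample
t-test uses a zero-centred Cauchy prior with scale sqrt(2)/2 on the
standardised effect (the JZS prior, integrated over its inverse-gamma g
representation); the correlation test uses a stretched beta prior with
kappa = 1 and the exact sampling distribution of r.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.optimize import brentq
from scipy.special import hyp2f1

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TestResult:
    """One inferential test: statistic, dfs, p, effect size, optional BF10."""

    __test__ = False  # not a pytest collection target

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float
    effect_size_name: str
    bf10: float | None = None
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def one_sample_t(values, mu0: float = 0.0, name: str = "one-sample t") -> TestResult:
    """Two-tailed one-sample t-test with Cohen's d = (mean - mu0) / SD."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero standard deviation")
    res = stats.ttest_1samp(x, mu0)
    return TestResult(name, float(res.statistic), len(x) - 1, float(res.pvalue),
                      float((x.mean() - mu0) / sd), "cohen_d")


def paired_t(a, b, name: str = "paired t") -> TestResult:
    return one_sample_t(np.asarray(a, float) - np.asarray(b, float), 0.0, name)


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> list[TestResult]:
    """Two-way (or one-way) repeated-measures ANOVA on a long table.

    Requires complete fully-crossed cases.  Partial eta squared is computed
    from F and the dfs (F*df1 / (F*df1 + df2)); for factors with >= 3 levels
    the Greenhouse-Geisser epsilon and corrected p are attached in ``extra``.
    """
    import pingouin as pg

    within = [within] if isinstance(within, str) else list(within)
    counts = data.groupby([subject] + within, observed=True)[dv].count().unstack(within)
    if counts.isna().any().any() or (counts < 1).any().any():
        raise ValueError("incomplete within-subject design: missing cells")

    table = pg.rm_anova(data=data, dv=dv, within=within if len(within) > 1 else within[0],
                        subject=subject, detailed=True)
    results = []
    for _, row in table.iterrows():
        if row.Source == "Error" or not np.isfinite(row.F):
            continue
        df1 = row.get("ddof1", row.get("DF"))
        df2 = row.get("ddof2")
        if df2 is None or (isinstance(df2, float) and np.isnan(df2)):
            # one-way pingouin layout: error df on the Error row
            df2 = float(table.loc[table.Source == "Error", "DF"].iloc[0])
        F = float(row.F)
        eta_p2 = F * df1 / (F * df1 + df2)
        extra = {}
        if "eps" in row and np.isfinite(row.eps) and df1 >= 2:
            extra["gg_epsilon"] = float(row.eps)
            if "p_GG_corr" in row and np.isfinite(row.get("p_GG_corr", np.nan)):
                extra["p_gg"] = float(row.p_GG_corr)
        results.append(TestResult(str(row.Source), F, (float(df1), float(df2)),
                                  float(row.p_unc), float(eta_p2),
                                  "partial_eta_squared", extra=extra))
    return results


# ---------------------------------------------------------------------------
# Bayes factors

def jzs_bf_ttest(t: float, n: int, scale: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor (BF10) for a one-sample t-test.

    Cauchy(0, scale) prior on the standardised effect under H1, point null
    under H0; computed by adaptive quadrature over the inverse-gamma g
    representation of the prior.
    """
    if n < 2 or not np.isfinite(t):
        raise ValueError("need n >= 2 and finite t")
    nu = n - 1
    r2 = scale ** 2

    def integrand(g):
        # likelihood ratio vs the null times the InvGamma(1/2, r^2/2) density
        lik = ((1 + n * g) ** -0.5
               * ((1 + t ** 2 / (nu * (1 + n * g))) / (1 + t ** 2 / nu)) ** (-(nu + 1) / 2))
        prior = (r2 / (2 * math.pi)) ** 0.5 * g ** -1.5 * math.exp(-r2 / (2 * g))
        return lik * prior

    bf, err = integrate.quad(integrand, 0, np.inf, epsrel=1e-10, epsabs=0, limit=400)
    if not np.isfinite(bf) or (bf > 0 and err / bf > 1e-6):
        raise ArithmeticError(f"JZS quadrature did not converge (bf={bf}, err={err})")
    return bf


def _corr_likelihood(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Sampling density of r given rho, up to rho-free factors (exact form
    with the Gaussian hypergeometric term)."""
    rho = np.asarray(rho, dtype=float)
    return ((1 - rho ** 2) ** ((n - 1) / 2)
            * (1 - rho * r) ** ((3 - 2 * n) / 2)
            * hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))


def _corr_loglik(r: float, rho, n: int):
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        return ((n - 1) / 2 * np.log1p(-rho ** 2)
                + (3 - 2 * n) / 2 * np.log1p(-rho * r)
                + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))


def jeffreys_bf_correlation(r: float, n: int, kappa: float = 1.0) -> float:
    """Default Bayes factor (BF10) for a Pearson correlation.

    Stretched beta prior on rho with width ``kappa`` (kappa = 1: uniform on
    [-1, 1]); exact likelihood; numerical quadrature, carried out in log space
    so large-n evidence does not overflow.  Symmetric in +/-r.
    """
    if not (abs(r) < 1) or n < 3:
        raise ValueError("need |r| < 1 and n >= 3")

    def prior(rho):
        return (1 - rho ** 2) ** (1 / kappa - 1)

    grid = np.linspace(-0.9995, 0.9995, 4001)
    shift = float(np.max(_corr_loglik(r, grid, n)))
    num, _ = integrate.quad(lambda rho: math.exp(_corr_loglik(r, rho, n) - shift)
                            * prior(rho), -1, 1, epsrel=1e-10, limit=400)
    z, _ = integrate.quad(prior, -1, 1, epsrel=1e-10, limit=400)
    log_bf = math.log(num / z) + shift - float(_corr_loglik(r, 0.0, n))
    bf = math.exp(log_bf) if log_bf < 700 else math.inf
    if num <= 0 or not np.isfinite(num):
        raise ArithmeticError("correlation BF quadrature failed")
    return bf


# ---------------------------------------------------------------------------
# correlations and power

def pearson_r(x, y, name: str = "pearson r") -> TestResult:
    """Product-moment correlation with t-based two-tailed p (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    t = r * math.sqrt((n - 2) / (1 - r ** 2)) if abs(r) < 1 else math.inf
    return TestResult(name, r, n - 2, float(res.pvalue), r, "r",
                      extra={"t": t, "n": n})


def t_test_power(d: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a one-sample t-test at standardised effect d (noncentral t)."""
    df = n - 1
    ncp = d * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / tails, df)
    power = float(np.nan_to_num(stats.nct.sf(tcrit, df, ncp)))
    if tails == 2:
        power += float(np.nan_to_num(stats.nct.cdf(-tcrit, df, ncp)))
    return power


def min_detectable_d(n: int, alpha: float = 0.05, power: float = 0.80,
                     tails: int = 2) -> float:
    """Smallest Cohen's d reaching the target power, by bisection on the
    noncentral-t power function (tolerance 1e-6)."""
    if not (0 < alpha < 1 and 0 < power < 1 and n > 1 and tails in (1, 2)):
        raise ValueError("invalid power query")
    f = lambda d: t_test_power(d, n, alpha, tails) - power
    hi = 0.1
    while f(hi) < 0:
        hi *= 2
        if hi > 100:
            raise ValueError("target power unattainable")
    root = brentq(f, 1e-9, hi, xtol=1e-8)
    while t_test_power(root, n, alpha, tails) < power:  # land on the >= side
        root += 1e-7
    return root


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80,
                     tails: int = 2) -> float:
    """Smallest detectable correlation via the Fisher-z approximation:
    r = tanh((z_{1-alpha/tails} + z_power) / sqrt(n - 3))."""
    if n <= 3 or tails not in (1, 2) or not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("invalid power query")
    za = stats.norm.ppf(1 - alpha / tails)
    zb = stats.norm.ppf(power)
    return math.tanh((za + zb) / math.sqrt(n - 3))
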