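"""Synthetic cohort generator.

Simulates trial-level behaviour for a cohort performing the rotated-character
task, with the statistical structure the downstream analyses assume:

* per-participant RTs follow a dual-viewpoint linear model,
  ``RT = gamma + beta_self * d_self + beta_other * d_other * [person present]
  + delta_move * [movement restricted]`` plus ex-Gaussian trial noise;
* a fixed number of "lapse" participants respond with error probabilities
  above the 20% exclusion cutoff, so the recruitment arithmetic of the
  emulated study (79 recruited, 61 retained) holds;
* questionnaire scores (age, AQ, IRI, STQ-STA) are tied to each participant's
  true other-viewpoint slope through a Gaussian copula, so the
  individual-differences analyses see realistic, attenuated correlations.

Everything is reproducible from the master seed in :class:`CohortConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import design
from .design import angular_disparity, enumerate_design, viewpoint_azimuth

__all__ = [
    "CohortConfig",
    "ParticipantParams",
    "sample_participant",
    "sample_cohort_params",
    "expected_rt",
    "simulate_trial",
    "simulate_cohort",
    "generate_questionnaires",
]

# Between-participant slope SDs derived from the group one-sample t statistics
# of the emulated study: SD = mean * sqrt(n) / t at n = 61.
_BETA_SELF_SD = 1.39 * math.sqrt(61) / 19.181
_BETA_OTHER_SD = 0.38 * math.sqrt(61) / 7.209


class CohortConfig(BaseModel):
    """Full generative specification of a synthetic cohort.

    Defaults are the "paper-default" study conditions: group-mean slopes equal
    the printed dual-regression coefficients, slope SDs are derived from the
    printed t statistics, 79 recruited of whom 18 lapse above the 20% error
    cutoff, ~8% errors otherwise, and questionnaire marginals/correlations
    match the reported individual-differences summaries.
    """

    seed: int
    n_recruited: int = 79
    n_lapse: int = 18

    gamma_mean: float = 750.0      # baseline RT, ms
    gamma_sd: float = 80.0
    beta_self_mean: float = 1.39   # ms per degree of disparity to participant
    beta_self_sd: float = _BETA_SELF_SD
    beta_other_mean: float = 0.38  # ms per degree of disparity to other person
    beta_other_sd: float = _BETA_OTHER_SD
    delta_move_mean: float = 15.0  # additive shift in restricted blocks, ms
    delta_move_sd: float = 0.0

    sigma: float = 60.0            # ex-Gaussian normal SD, ms
    tau: float = 100.0             # ex-Gaussian exponential mean, ms
    rt_floor: float = 150.0        # ms, truncation below
    rt_ceiling: float = 3500.0     # ms, response window censoring

    p_error: float = 0.08
    lapse_p_error_range: tuple[float, float] = (0.25, 0.40)
    error_slope: float = 0.0       # optional error-rate increase per degree d_self

    # questionnaire marginals
    age_range: tuple[int, int] = (18, 35)
    age_decay: float = 0.72        # geometric decay of the skewed-young age pmf
    aq_mean: float = 16.64
    aq_sd: float = 6.29
    iri_mean: float = 68.45
    iri_sd: float = 11.34
    stq_p: float = 0.30            # binomial-like STA marginal over 37 items
    n_missing_questionnaire: int = 3

    # target correlations of the latent perspective-taking propensity
    # (the participant's true beta_other) with each trait
    corr_age: float = 0.38
    corr_stq: float = -0.26
    corr_aq: float = 0.0
    corr_iri: float = 0.0

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        if self.n_lapse > self.n_recruited:
            raise ValueError("n_lapse cannot exceed n_recruited")
        for name in ("gamma_sd", "beta_self_sd", "beta_other_sd", "delta_move_sd",
                     "sigma", "tau", "aq_sd", "iri_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_error <= 1:
            raise ValueError("p_error must lie in [0, 1]")
        lo, hi = self.lapse_p_error_range
        if not (0.20 < lo <= hi <= 1.0):
            raise ValueError("lapse error probabilities must lie in (0.20, 1]")
        rho = self.trait_correlations()
        if np.any(np.abs(list(rho.values())) > 1):
            raise ValueError("trait correlations must lie in [-1, 1]")
        # latent model: trait_i = rho_i * z + sqrt(1-rho_i^2) * eps_i; the
        # implied (traits + propensity) correlation matrix is PSD iff |rho|<=1,
        # but check explicitly so hand-edited matrices fail loudly.
        r = np.array(list(rho.values()))
        m = np.outer(r, r)
        np.fill_diagonal(m, 1.0)
        m = np.vstack([np.column_stack([m, r]), np.append(r, 1.0)])
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("implied trait correlation matrix is not PSD")
        return self

    def trait_correlations(self) -> dict[str, float]:
        return {"age": self.corr_age, "stq_sta": self.corr_stq,
                "aq_total": self.corr_aq, "iri_total": self.corr_iri}

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2)


@dataclasses.dataclass
class ParticipantParams:
    """Generative parameters of one simulated participant."""

    participant_id: str
    gamma: float
    beta_self: float
    beta_other: float
    delta_move: float
    p_error: float
    lapse: bool

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("baseline RT gamma must be positive")
        if not 0 <= self.p_error <= 1:
            raise ValueError("p_error must lie in [0, 1]")
        if self.lapse and self.p_error <= 0.20:
            raise ValueError("lapse participants must have p_error > 0.20")


def sample_participant(config: CohortConfig, rng: np.random.Generator,
                       participant_id: str = "p001", lapse: bool = False) -> ParticipantParams:
    """Draw one participant's generative parameters from the configured normals."""
    lo, hi = config.lapse_p_error_range
    return ParticipantParams(
        participant_id=participant_id,
        gamma=max(rng.normal(config.gamma_mean, config.gamma_sd), 1.0),
        beta_self=rng.normal(config.beta_self_mean, config.beta_self_sd),
        beta_other=rng.normal(config.beta_other_mean, config.beta_other_sd),
        delta_move=rng.normal(config.delta_move_mean, config.delta_move_sd),
        p_error=rng.uniform(lo, hi) if lapse else config.p_error,
        lapse=lapse,
    )


def sample_cohort_params(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw all recruited participants; exactly ``n_lapse`` are lapse-flagged
    (uniformly at random among the recruited)."""
    lapse_ids = set(rng.choice(config.n_recruited, size=config.n_lapse, replace=False))
    rows = []
    for i in range(config.n_recruited):
        p = sample_participant(config, rng, participant_id=f"p{i + 1:03d}",
                               lapse=i in lapse_ids)
        rows.append(dataclasses.asdict(p))
    return pd.DataFrame(rows)


def expected_rt(spec, params) -> float:
    """Deterministic linear predictor of a trial's RT in ms.

    ``spec`` needs fields movement, person_location, orientation_deg; ``params``
    needs gamma, beta_self, beta_other, delta_move.  Works on scalars or on a
    design DataFrame + params row (vectorised).
    """
    theta = np.asarray(getattr(spec, "orientation_deg"), dtype=float)
    location = np.asarray(getattr(spec, "person_location"))
    movement = np.asarray(getattr(spec, "movement"))
    d_self = angular_disparity(theta, viewpoint_azimuth("participant"))
    phi = np.where(location == "left", 90.0, 270.0)
    d_other = np.where(location == "none", 0.0, angular_disparity(theta, phi))
    other_present = (location != "none").astype(float)
    restricted = (movement == "restricted").astype(float)
    rt = (params.gamma
          + params.beta_self * d_self
          + params.beta_other * d_other * other_present
          + params.delta_move * restricted)
    return float(rt) if np.ndim(rt) == 0 else rt


def _ex_gaussian(rng: np.random.Generator, sigma: float, tau: float, size) -> np.ndarray:
    shape = () if size is None else size
    noise = rng.normal(0.0, sigma, size=size) if sigma > 0 else np.zeros(shape)
    if tau > 0:
        noise = noise + rng.exponential(tau, size=size)
    return noise


def simulate_trial(spec, params, config: CohortConfig, rng: np.random.Generator):
    """Simulate one trial: (rt_ms, correct).

    RT is the linear predictor plus ex-Gaussian noise, truncated below at the
    RT floor and censored at the response window; correctness is Bernoulli and
    independent of the RT draw.
    """
    mu = expected_rt(spec, params)
    rt = mu + float(_ex_gaussian(rng, config.sigma, config.tau, None))
    rt = min(max(rt, config.rt_floor), config.rt_ceiling)
    d_self = angular_disparity(float(spec.orientation_deg), 0.0)
    p_err = float(np.clip(params.p_error + config.error_slope * d_self, 0.0, 1.0))
    correct = bool(rng.random() >= p_err)
    return rt, correct


def _simulate_participant_trials(p_row, config: CohortConfig,
                                 rng: np.random.Generator,
                                 movement_first: str) -> pd.DataFrame:
    trials = enumerate_design(rng, movement_first=movement_first)
    params = ParticipantParams(**{k: p_row[k] for k in
                                  ("participant_id", "gamma", "beta_self", "beta_other",
                                   "delta_move", "p_error", "lapse")})
    mu = expected_rt(trials, params)
    rt = mu + _ex_gaussian(rng, config.sigma, config.tau, len(trials))
    rt = np.clip(rt, config.rt_floor, config.rt_ceiling)
    d_self = angular_disparity(trials.orientation_deg.to_numpy(float), 0.0)
    p_err = np.clip(params.p_error + config.error_slope * d_self, 0.0, 1.0)
    correct = rng.random(len(trials)) >= p_err
    trials = trials.copy()
    trials.insert(0, "participant_id", params.participant_id)
    # the recorded keypress: the true form when correct, the other one otherwise
    other = np.where(trials.form == "canonical", "mirror", "canonical")
    trials["response"] = np.where(correct, trials.form, other)
    trials["correct"] = correct
    trials["rt_ms"] = np.round(rt, 3)
    return trials


def simulate_cohort(config: CohortConfig):
    """Simulate the full cohort.

    Returns ``(trials, questionnaires, participants)``: the trial table (one
    row per trial, n_recruited x 576 rows), the questionnaire table, and the
    true generative parameters per participant.  Deterministic given the
    config's master seed.
    """
    rng = np.random.default_rng(config.seed)
    params = sample_cohort_params(config, rng)
    frames = []
    for i, row in params.iterrows():
        movement_first = design.MOVEMENTS[i % 2]  # ABAB / BABA counterbalanced
        frames.append(_simulate_participant_trials(row, config, rng, movement_first))
    trials = pd.concat(frames, ignore_index=True)
    questionnaires = generate_questionnaires(params, config, rng)
    return trials, questionnaires, params


# ---------------------------------------------------------------------------
# questionnaires

def _age_quantile(u: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Discrete skewed-young age marginal: P(age = lo + k) ~ decay^k."""
    lo, hi = config.age_range
    k = np.arange(hi - lo + 1)
    pmf = config.age_decay ** k
    cdf = np.cumsum(pmf) / pmf.sum()
    return lo + np.searchsorted(cdf, u, side="left")


def _trunc_normal_quantile(u, mean, sd, lo, hi):
    from scipy.stats import truncnorm
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_questionnaires(params: pd.DataFrame, config: CohortConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Questionnaire totals tied to the true other-viewpoint slope.

    A Gaussian copula correlates each trait's latent normal with the
    participant's standardised true ``beta_other`` (the generative
    perspective-taking propensity) at the configured target, then maps it to
    the trait's marginal: age discrete 18-35 skewed young, AQ truncated normal
    0-50, IRI truncated normal 0-112 (split into four subscales), STQ-STA
    binomial over 37 items.  ``n_missing_questionnaire`` non-lapse participants
    get missing AQ/IRI/STQ scores (age, from recruitment, is always present).
    """
    from scipy.stats import binom, norm

    n = len(params)
    if config.beta_other_sd > 0:
        z_prop = (params.beta_other.to_numpy() - config.beta_other_mean) / config.beta_other_sd
    else:  # degenerate propensity: traits are independent of it
        z_prop = np.zeros(n)
    out = pd.DataFrame({"participant_id": params.participant_id})

    def latent(rho):
        return rho * z_prop + math.sqrt(1 - rho ** 2) * rng.normal(size=n)

    u_age = norm.cdf(latent(config.corr_age))
    out["age"] = _age_quantile(u_age, config).astype(int)

    u_aq = norm.cdf(latent(config.corr_aq))
    out["aq_total"] = np.rint(_trunc_normal_quantile(u_aq, config.aq_mean, config.aq_sd, 0, 50)).astype(int)

    u_iri = norm.cdf(latent(config.corr_iri))
    iri = np.rint(_trunc_normal_quantile(u_iri, config.iri_mean, config.iri_sd, 0, 112)).astype(int)
    out["iri_total"] = iri
    subs = _allocate_iri_subscales(iri)
    for name, vals in subs.items():
        out[name] = vals

    u_stq = norm.cdf(latent(config.corr_stq))
    out["stq_sta"] = binom.ppf(u_stq, 37, config.stq_p).astype(int)

    if config.n_missing_questionnaire > 0:
        candidates = np.flatnonzero(~params.lapse.to_numpy())
        missing = rng.choice(candidates, size=config.n_missing_questionnaire, replace=False)
        cols = ["aq_total", "iri_total", "iri_pt", "iri_ec", "iri_fs", "iri_pd", "stq_sta"]
        out.loc[missing, cols] = np.nan
    return out


def _allocate_iri_subscales(total: np.ndarray) -> dict[str, np.ndarray]:
    """Split each IRI total into four 0-28 subscales by largest remainder, so
    the subscales sum exactly to the total."""
    names = ["iri_pt", "iri_ec", "iri_fs", "iri_pd"]
    base = total // 4
    rem = total - 4 * base
    parts = np.tile(base[:, None], (1, 4))
    for j in range(4):
        parts[:, j] += (rem > j).astype(int)
    # cap at 28 and push overflow to the emptiest subscale
    for _ in range(4):
        over = parts - 28
        over[over < 0] = 0
        if not over.any():
            break
        parts -= over
        receiver = np.argmin(parts, axis=1)
        parts[np.arange(len(parts)), receiver] += over.sum(axis=1)
    return {name: parts[:, j] for j, name in enumerate(names)}
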