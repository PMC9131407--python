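"""End-to-end orchestration: simulate -> preprocess -> biases -> regressions
-> inference -> individual differences.

``run_simulate`` writes the trial and questionnaire CSVs for a configured
cohort; ``run_analyze`` reads them back (or any table in the same dialect)
and emits the result tables mirroring the study's Results structure, plus a
run manifest tracing every output to the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import bias_table, error_rate_biases, perspective_scores
from .cohort import CohortConfig, simulate_cohort
from .inference import jzs_bf_ttest, one_sample_t, rm_anova
from .preprocess import exclude_participants, filter_trials, orientation_profiles
from .regression import fit_cohort, summarise_fits
from .traits import hierarchical_regression, trait_correlations

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant_id", "block", "trial_index", "movement",
                 "person_location", "actor_sex", "character", "form",
                 "orientation_deg", "response", "correct", "rt_ms"]


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulate(config: CohortConfig, outdir) -> dict:
    """Simulate a cohort and write trials.csv, questionnaires.csv,
    participants.csv and manifest.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, quest, params = simulate_cohort(config)
    trials.to_csv(outdir / "trials.csv", index=False)
    quest.to_csv(outdir / "questionnaires.csv", index=False)
    params.to_csv(outdir / "participants.csv", index=False)
    manifest = {
        "stage": "simulate",
        "vptlab_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_participants": int(trials.participant_id.nunique()),
        "n_trials": int(len(trials)),
        "outputs": ["trials.csv", "questionnaires.csv", "participants.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_json(outdir / "config.json")
    return manifest


def _require_columns(df: pd.DataFrame, cols, label: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{label} is missing required columns: {missing}")


def analyze(trials: pd.DataFrame, questionnaires: pd.DataFrame | None = None) -> dict:
    """Run the full analysis on a trial table (and optional questionnaires).

    Returns a bundle of result tables:

    - ``mental_rotation``: per-condition towards/away biases, the overall bias
      t-test, and the simple self-rotation slope summary;
    - ``ta_anova``: 2 x 3 movement x location ANOVA on towards/away biases;
    - ``lr_anova``: 2 x 2 movement x location (left/right) ANOVA on left/right
      biases, plus per-movement person-left vs person-right contrasts;
    - ``regression``: dual-viewpoint coefficient summaries per scope and the
      2 x 2 movement x viewpoint ANOVA on the coefficients;
    - ``error_biases``: error-rate bias table in the published layout;
    - ``individual_differences``: trait correlations + hierarchical regression
      (participants without questionnaires are analysed in the behavioural
      stages and dropped, with a log entry, here);
    - ``manifest``: inclusion ledger and per-stage counts.
    """
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    retained, exclusion_report = exclude_participants(trials)
    logger.info("retained %d of %d participants", len(retained),
                trials.participant_id.nunique())
    kept = trials[trials.participant_id.isin(retained)]
    filt = filter_trials(kept)

    profiles_rt = orientation_profiles(filt.rt_stream, "rt_ms")
    profiles_err = orientation_profiles(filt.error_stream, "error_rate")
    biases_rt = bias_table(profiles_rt)
    biases_err = error_rate_biases(profiles_err)

    bundle: dict = {"exclusions": exclusion_report, "filter_log": filt.log,
                    "biases_rt": biases_rt, "biases_err": biases_err}

    # --- mental rotation -------------------------------------------------
    pooled = biases_rt[biases_rt.movement == "pooled"]
    overall_ta = pooled.groupby("participant_id").ta_bias.mean().dropna()
    ta_test = one_sample_t(overall_ta.to_numpy(), name="towards/away bias vs 0")
    self_fits = fit_cohort(profiles_rt, kind="self", scope="all")
    self_summary = summarise_fits(self_fits, "beta_self")
    bundle["mental_rotation"] = {
        "ta_mean": float(overall_ta.mean()),
        "ta_sd": float(overall_ta.std(ddof=1)),
        "ta_test": ta_test,
        "ta_bf10": jzs_bf_ttest(ta_test.statistic, len(overall_ta)),
        "self_slope_summary": self_summary,
    }

    # --- ANOVAs on biases -------------------------------------------------
    long_ta = biases_rt[biases_rt.movement.isin(["free", "restricted"])].dropna(
        subset=["ta_bias"])
    bundle["ta_anova"] = rm_anova(long_ta, dv="ta_bias",
                                  within=["movement", "person_location"],
                                  subject="participant_id")
    long_lr = long_ta[long_ta.person_location.isin(["left", "right"])]
    bundle["lr_anova"] = rm_anova(long_lr, dv="lr_bias",
                                  within=["movement", "person_location"],
                                  subject="participant_id")
    contrasts = {}
    for movement in ("free", "restricted"):
        sub = long_lr[long_lr.movement == movement].pivot(
            index="participant_id", columns="person_location", values="lr_bias").dropna()
        diff = (sub["left"] - sub["right"]).to_numpy()
        test = one_sample_t(diff, name=f"left vs right person, {movement}")
        test.bf10 = jzs_bf_ttest(test.statistic, len(diff))
        contrasts[movement] = test
    bundle["lr_contrasts"] = contrasts

    # --- dual-viewpoint regressions --------------------------------------
    reg = {}
    fits_by_scope = {}
    for scope in ("all", "free", "restricted"):
        fits = fit_cohort(profiles_rt, kind="dual", scope=scope)
        fits_by_scope[scope] = fits
        reg[scope] = {c: summarise_fits(fits, c) for c in ("beta_self", "beta_other")}
    long_beta = pd.concat([
        fits_by_scope[m].melt(id_vars="participant_id",
                              value_vars=["beta_self", "beta_other"],
                              var_name="viewpoint", value_name="beta")
        .assign(movement=m)
        for m in ("free", "restricted")], ignore_index=True).dropna(subset=["beta"])
    reg["beta_anova"] = rm_anova(long_beta, dv="beta",
                                 within=["movement", "viewpoint"],
                                 subject="participant_id")
    bundle["regression"] = reg
    bundle["dual_fits"] = fits_by_scope["all"]

    # --- error-rate biases (published table layout) -----------------------
    rows = []
    for movement, label in (("pooled", "All"), ("free", "Free-movement"),
                            ("restricted", "No-movement")):
        row = {"condition": label}
        sub = biases_err[biases_err.movement == movement]
        for kind in ("ta_bias", "lr_bias"):
            for loc in ("left", "right", "none"):
                cell = sub[sub.person_location == loc][kind].dropna()
                row[f"{kind}_{loc}_mean"] = float(cell.mean())
                row[f"{kind}_{loc}_sd"] = float(cell.std(ddof=1))
        rows.append(row)
    bundle["error_biases"] = pd.DataFrame(rows)

    # --- perspective-taking scores and individual differences -------------
    pt = perspective_scores(biases_rt, movement="pooled").dropna()
    pt_test = one_sample_t(pt.pt_score.to_numpy(), name="perspective-taking score vs 0")
    pt_test.bf10 = jzs_bf_ttest(pt_test.statistic, len(pt))
    bundle["pt_scores"] = pt
    bundle["pt_test"] = pt_test

    if questionnaires is not None:
        _require_columns(questionnaires, ["participant_id"], "questionnaire table")
        merged = pt.merge(questionnaires, on="participant_id", how="left")
        n_missing = int(merged.drop(columns=["participant_id", "pt_score"])
                        .isna().any(axis=1).sum())
        if n_missing:
            logger.info("%d participants lack questionnaire data; dropped from "
                        "individual-differences stages only", n_missing)
        bundle["trait_correlations"] = trait_correlations(pt, questionnaires)
        try:
            steps, full_model = hierarchical_regression(pt, questionnaires)
            bundle["hierarchical"] = {"steps": steps, "full_model": full_model}
        except ValueError as err:
            logger.warning("hierarchical regression skipped: %s", err)
            bundle["hierarchical"] = None

    bundle["manifest"] = {
        "stage": "analyze",
        "vptlab_version": __version__,
        "n_input_participants": int(trials.participant_id.nunique()),
        "n_retained": len(retained),
        "filter_log": filt.log,
        "inclusion": exclusion_report.to_dict(orient="records"),
    }
    return bundle


def run_analyze(trials_csv, questionnaires_csv=None, outdir=None) -> dict:
    """File-level wrapper around :func:`analyze`; writes the report bundle as
    CSV/JSON under ``outdir`` when given."""
    trials = pd.read_csv(trials_csv)
    quest = pd.read_csv(questionnaires_csv) if questionnaires_csv else None
    bundle = analyze(trials, quest)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _jsonable(obj):
    import dataclasses as dc
    if dc.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dc.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_bundle(bundle: dict, outdir) -> None:
    """Persist the analysis bundle: DataFrames as CSV, the rest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=False)
        else:
            summary[key] = _jsonable(val)
    (outdir / "results.json").write_text(json.dumps(summary, indent=2))


def replicate_recovery(master_seed: int, n_replicates: int = 8,
                       config_overrides: dict | None = None) -> dict:
    """Parameter-recovery summary over independent replicate cohorts.

    Simulates ``n_replicates`` paper-default cohorts (seeds derived from
    ``master_seed``), runs exclusion, filtering, orientation profiling and the
    per-participant dual-viewpoint regressions on each, and returns the
    across-replicate average of the cohort-mean coefficients (per scope) and
    of the cohort-mean towards/away bias.  Averaging over replicates reduces
    the Monte-Carlo error of the estimated expectation; each individual
    cohort remains a faithful draw from the generative configuration.
    """
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    acc: dict[str, list] = {}

    def push(key, val):
        acc.setdefault(key, []).append(val)

    for s in seeds:
        cfg = CohortConfig(seed=int(s), **(config_overrides or {}))
        trials, _, _ = simulate_cohort(cfg)
        retained, _ = exclude_participants(trials)
        kept = trials[trials.participant_id.isin(retained)]
        filt = filter_trials(kept)
        prof = orientation_profiles(filt.rt_stream, "rt_ms")
        for scope in ("all", "free", "restricted"):
            fits = fit_cohort(prof, kind="dual", scope=scope)
            push(f"beta_self_{scope}", fits.beta_self.mean())
            push(f"beta_other_{scope}", fits.beta_other.mean())
        biases = bias_table(prof)
        pooled = biases[biases.movement == "pooled"]
        push("ta_bias", pooled.groupby("participant_id").ta_bias.mean().mean())
        push("n_retained", len(retained))
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["n_replicates"] = n_replicates
    out["n_participants_total"] = int(np.sum(acc["n_retained"]))
    return out


def render_report(bundle: dict) -> str:
    """Human-readable text report mirroring the Results subsections.

    ANOVA Bayes factors are printed as n/a (out of scope): only t-test and
    correlation Bayes factors are implemented.
    """
    lines = ["# Mental rotation"]
    mr = bundle["mental_rotation"]
    t = mr["ta_test"]
    lines.append(f"towards/away bias M = {mr['ta_mean']:.2f} ms, SD = {mr['ta_sd']:.2f}, "
                 f"t({t.df}) = {t.statistic:.2f}, p = {t.p:.2g}, d = {t.effect_size:.2f}, "
                 f"BF10 = {mr['ta_bf10']:.4g}")
    s = mr["self_slope_summary"]
    lines.append(f"simple self-rotation slope mean beta = {s['mean']:.2f} ms/deg "
                 f"({s['n_positive']}/{s['n']} positive), t({s['df']}) = {s['t']:.2f}, "
                 f"BF10 = {s['bf10']:.4g}")
    for key, title in (("ta_anova", "2x3 ANOVA on towards/away biases"),
                       ("lr_anova", "2x2 ANOVA on left/right biases")):
        lines.append(f"\n# {title}")
        for res in bundle[key]:
            df1, df2 = res.df
            lines.append(f"{res.name}: F({df1:.0f},{df2:.0f}) = {res.statistic:.3f}, "
                         f"p = {res.p:.3g}, partial eta2 = {res.effect_size:.3f}, "
                         f"BF10 = n/a (out of scope)")
    lines.append("\n# Perspective taking")
    pt = bundle["pt_test"]
    lines.append(f"perspective-taking score vs 0: t({pt.df}) = {pt.statistic:.2f}, "
                 f"p = {pt.p:.2g}, d = {pt.effect_size:.2f}, BF10 = {pt.bf10:.4g}")
    for movement, res in bundle["lr_contrasts"].items():
        lines.append(f"left vs right person ({movement}): t({res.df}) = {res.statistic:.2f}, "
                     f"p = {res.p:.2g}, d = {res.effect_size:.2f}, BF10 = {res.bf10:.4g}")
    lines.append("\n# Regression analysis")
    for scope in ("all", "free", "restricted"):
        for coef in ("beta_self", "beta_other"):
            s = bundle["regression"][scope][coef]
            lines.append(f"{scope:10s} {coef}: mean = {s['mean']:.3f} ms/deg, "
                         f"t({s['df']}) = {s['t']:.2f}, d = {s['d']:.2f}, "
                         f"BF10 = {s['bf10']:.4g}")
    if "trait_correlations" in bundle:
        lines.append("\n# Individual differences")
        for _, row in bundle["trait_correlations"].iterrows():
            lines.append(f"pt ~ {row.predictor}: r = {row.r:.3f}, p = {row.p:.3g}, "
                         f"BF10 = {row.bf10:.3g} (n = {row.n:.0f})")
        if bundle.get("hierarchical") is None:
            return "\n".join(lines + ["hierarchical regression: skipped (degenerate input)"])
        for step in bundle["hierarchical"]["steps"]:
            df1, df2 = step.df
            lines.append(f"step {'+'.join(step.predictors)}: R2 = {step.r_squared:.3f}, "
                         f"dR2 = {step.delta_r_squared:.3f}, "
                         f"F({df1},{df2}) = {step.f_change:.3f}, p = {step.p_change:.3g}")
    return "\n".join(lines)
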