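"""Per-participant mental-rotation regressions and group summaries.

Fits the simple self-disparity regression and the 16-cell dual-viewpoint
regression per participant (overall and per movement condition), summarises
the coefficients with one-sample t-tests and JZS Bayes factors, and runs the
2x2 movement x viewpoint ANOVA on the dual coefficients.  Writes tables under
results/regression/.
"""

from pathlib import Path

import pandas as pd

from vptlab.design import ORIENTATIONS
from vptlab.inference import rm_anova
from vptlab.regression import fit_cohort, summarise_fits

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    prof = pd.read_csv(ROOT / "preprocessed" / "profiles_rt.csv").rename(
        columns={str(t): t for t in ORIENTATIONS})
    out = ROOT / "regression"
    out.mkdir(parents=True, exist_ok=True)

    summaries = []
    fits_by_scope = {}
    for scope in ("all", "free", "restricted"):
        fits = fit_cohort(prof, kind="dual", scope=scope)
        fits_by_scope[scope] = fits
        fits.to_csv(out / f"dual_fits_{scope}.csv", index=False)
        for coef in ("beta_self", "beta_other"):
            s = summarise_fits(fits, coef)
            s["scope"] = scope
            summaries.append(s)
            print(f"{scope:10s} {coef}: mean = {s['mean']:.3f} ms/deg "
                  f"(SD {s['sd']:.3f}), t({s['df']}) = {s['t']:.2f}, "
                  f"d = {s['d']:.2f}, BF10 = {s['bf10']:.3g}, "
                  f"{s['n_positive']}/{s['n']} positive")
    pd.DataFrame(summaries).to_csv(out / "coefficient_summaries.csv", index=False)

    simple = fit_cohort(prof, kind="self", scope="all")
    simple.to_csv(out / "self_fits_all.csv", index=False)
    s = summarise_fits(simple, "beta_self")
    print(f"\nsimple self-rotation slope: mean = {s['mean']:.3f} ms/deg, "
          f"t({s['df']}) = {s['t']:.2f}, {s['n_positive']}/{s['n']} positive")

    long = pd.concat([
        fits_by_scope[m].melt(id_vars="participant_id",
                              value_vars=["beta_self", "beta_other"],
                              var_name="viewpoint", value_name="beta").assign(movement=m)
        for m in ("free", "restricted")], ignore_index=True).dropna(subset=["beta"])
    print("\n2x2 movement x viewpoint ANOVA on coefficients:")
    for r in rm_anova(long, dv="beta", within=["movement", "viewpoint"],
                      subject="participant_id"):
        print(f"  {r.name}: F({r.df[0]:.0f},{r.df[1]:.0f}) = {r.statistic:.3f}, "
              f"p = {r.p:.3g}, partial eta2 = {r.effect_size:.3f}")
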