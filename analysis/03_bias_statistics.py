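"""Vector-projection bias statistics and their within-subject ANOVAs.

Computes towards/away and left/right biases per participant and condition,
the perspective-taking scores, the 2x3 (movement x location) ANOVA on
towards/away biases, the 2x2 ANOVA on left/right biases, and the error-rate
bias table.  Writes tables under results/biases/.
"""

from pathlib import Path

import pandas as pd

from vptlab.bias import bias_table, error_rate_biases, perspective_scores
from vptlab.design import ORIENTATIONS
from vptlab.inference import jzs_bf_ttest, one_sample_t, rm_anova

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    prof_rt = pd.read_csv(ROOT / "preprocessed" / "profiles_rt.csv").rename(
        columns={str(t): t for t in ORIENTATIONS})
    prof_err = pd.read_csv(ROOT / "preprocessed" / "profiles_error.csv").rename(
        columns={str(t): t for t in ORIENTATIONS})
    biases = bias_table(prof_rt)
    err_biases = error_rate_biases(prof_err)
    pt = perspective_scores(biases).dropna()

    out = ROOT / "biases"
    out.mkdir(parents=True, exist_ok=True)
    biases.to_csv(out / "rt_biases.csv", index=False)
    err_biases.to_csv(out / "error_biases.csv", index=False)
    pt.to_csv(out / "perspective_scores.csv", index=False)

    pooled = biases[biases.movement == "pooled"]
    ta = pooled.groupby("participant_id").ta_bias.mean().dropna()
    test = one_sample_t(ta.to_numpy())
    print(f"towards/away bias: M = {ta.mean():.2f} ms, SD = {ta.std(ddof=1):.2f}, "
          f"t({test.df}) = {test.statistic:.2f}, d = {test.effect_size:.2f}, "
          f"BF10 = {jzs_bf_ttest(test.statistic, len(ta)):.3g}")

    long = biases[biases.movement.isin(["free", "restricted"])]
    for name, frame, dv in (
            ("2x3 ANOVA on towards/away biases", long, "ta_bias"),
            ("2x2 ANOVA on left/right biases",
             long[long.person_location.isin(["left", "right"])], "lr_bias")):
        print(f"\n{name}:")
        results = rm_anova(frame, dv=dv, within=["movement", "person_location"],
                           subject="participant_id")
        pd.DataFrame([{"effect": r.name, "F": r.statistic, "df1": r.df[0],
                       "df2": r.df[1], "p": r.p, "partial_eta_sq": r.effect_size}
                      for r in results]).to_csv(
            out / f"anova_{dv}.csv", index=False)
        for r in results:
            print(f"  {r.name}: F({r.df[0]:.0f},{r.df[1]:.0f}) = {r.statistic:.3f}, "
                  f"p = {r.p:.3g}, partial eta2 = {r.effect_size:.3f}")

    pt_test = one_sample_t(pt.pt_score.to_numpy())
    print(f"\nperspective-taking score: M = {pt.pt_score.mean():.2f} ms, "
          f"t({pt_test.df}) = {pt_test.statistic:.2f}, "
          f"BF10 = {jzs_bf_ttest(pt_test.statistic, len(pt)):.3g}")
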