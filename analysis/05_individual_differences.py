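"""Individual differences: trait correlations and hierarchical regression.

Correlates the spontaneous perspective-taking score with age, STQ-STA, AQ and
IRI totals (Pearson r, p, stretched-beta BF10), then enters the predictors
hierarchically (age, STQ, AQ, IRI) into nested OLS models with
R-squared-change F-tests.  Writes tables under results/individual_differences/.
"""

from pathlib import Path

import pandas as pd

from vptlab.traits import hierarchical_regression, trait_correlations

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    pt = pd.read_csv(ROOT / "biases" / "perspective_scores.csv")
    quest = pd.read_csv(ROOT / "cohort" / "questionnaires.csv")
    out = ROOT / "individual_differences"
    out.mkdir(parents=True, exist_ok=True)

    corr = trait_correlations(pt, quest)
    corr.to_csv(out / "trait_correlations.csv", index=False)
    for _, row in corr.iterrows():
        print(f"pt ~ {row.predictor}: r = {row.r:.3f}, p = {row.p:.3g}, "
              f"BF10 = {row.bf10:.3g} (n = {row.n})")

    steps, full = hierarchical_regression(pt, quest)
    pd.DataFrame([{"step": "+".join(s.predictors), "r_squared": s.r_squared,
                   "delta_r_squared": s.delta_r_squared, "f_change": s.f_change,
                   "df1": s.df[0], "df2": s.df[1], "p_change": s.p_change}
                  for s in steps]).to_csv(out / "hierarchical_steps.csv", index=False)
    full.to_csv(out / "full_model_betas.csv", index=False)

    print("\nhierarchical entry (age, STQ, AQ, IRI):")
    for s in steps:
        print(f"  + {s.predictors[-1]}: R2 = {s.r_squared:.3f} "
              f"(dR2 = {s.delta_r_squared:.3f}), F({s.df[0]},{s.df[1]}) = "
              f"{s.f_change:.3f}, p = {s.p_change:.3g}")
    print("\nfull-model standardized betas:")
    for _, row in full.iterrows():
        print(f"  {row.predictor}: beta = {row.beta_std:.3f}, "
              f"t = {row.t:.2f}, p = {row.p:.3g}")
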