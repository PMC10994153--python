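#!/usr/bin/env python
"""Cross-sectional association battery.

Spearman correlations of shape dummies and standardized FPC scores against
timed glucose/insulin values and metabolic labs (Bonferroni at 0.05/171),
Kruskal-Wallis / Fisher tests of demographics and labs across shape
classes, and demographic-adjusted linear models of each FPC on each lab.
"""

import argparse
from pathlib import Path

import pandas as pd

from ogttfda import associations, shapes
from ogttfda.cohort import read_cohort, records_to_frame
from ogttfda.config import PipelineConfig
from ogttfda.pipeline import LAB_TARGETS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--scores", type=Path, default=Path("results/scores.csv"))
    ap.add_argument("--shapes", type=Path, default=Path("results/shapes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig()
    demo = records_to_frame(read_cohort(args.cohort).records)
    scores = pd.read_csv(args.scores)
    shp = pd.read_csv(args.shapes)

    dummies = shapes.shape_dummies(shp["shape"])
    print(f"{dummies.attrs['n_excluded']} participant(s) with inconclusive "
          "shape excluded from shape-coded associations")
    std_cols = [c for c in scores.columns
                if c.endswith(("fpc1", "fpc2", "fpc3"))]
    features = pd.concat([dummies.add_prefix("shape_"),
                          scores.loc[dummies.index, std_cols]], axis=1)
    tcols = [f"{a}_{t}" for a in ("glucose", "insulin")
             for t in (0, 30, 60, 90, 120)] + LAB_TARGETS
    spear = associations.spearman_matrix(
        features, demo.loc[dummies.index, tcols],
        alpha=cfg.bonferroni_alpha, n_comparisons=cfg.bonferroni_n)
    spear.to_csv(args.out / "spearman.csv", index=False)
    n_sig = int(spear["significant"].sum())
    print(f"{n_sig}/{len(spear)} pairs significant at p < "
          f"{cfg.bonferroni_threshold:.2e}")
    for f, t in (("glu_fpc1", "bmi_percentile"),
                 ("ins_fpc1", "triglycerides"),
                 ("shape_monophasic", "glucose_60"),
                 ("shape_biphasic", "glucose_60")):
        row = spear[(spear.feature == f) & (spear.target == t)].iloc[0]
        print(f"  {f} vs {t}: r = {row.spearman_r:+.2f} "
              f"(p = {row.p_value:.2g}, n = {row.n})")

    group = associations.group_difference_tests(
        shp.loc[dummies.index, "shape"],
        pd.concat([demo.loc[dummies.index,
                            ["age", "sex", "race", "ethnicity"]],
                   demo.loc[dummies.index, LAB_TARGETS]], axis=1),
        categorical=["sex", "race", "ethnicity"])
    group.to_csv(args.out / "group_tests.csv", index=False)

    adjusted = associations.adjusted_fpc_models(
        scores[std_cols], demo[LAB_TARGETS],
        demo[["age", "sex", "race", "ethnicity"]])
    adjusted.to_csv(args.out / "adjusted_models.csv", index=False)
    print(f"wrote spearman, group_tests and adjusted_models to {args.out}/")


if __name__ == "__main__":
    main()
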