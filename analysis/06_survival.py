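#!/usr/bin/env python
"""Cohort associations and survival.

Runs the association battery (density/richness/clonality correlations,
compartment comparisons) and the survival stage: median-dichotomized
log-rank + univariate Cox, then multivariate Cox adjusted for age, sex,
histology, stage, smoking and tumor size, for blood T cell density,
adjacent-lung density and lung-enriched clonality. With the planted hazard
(protective blood density, harmful lung-enriched clonality) the expected
picture is HR < 1 for the former and HR > 1 for the latter. Writes
results/associations.csv and results/survival.csv.
"""

import pandas as pd
from _common import RESULTS, load_samples

from tcrrep import pipeline, stats


def main() -> None:
    manifest, samples = load_samples()
    metrics = pd.read_csv(RESULTS / "metrics.csv")
    lec = pd.read_csv(RESULTS / "lung_enriched_clonality.csv")

    tumor = metrics[metrics["compartment"] == "TUMOR"].set_index("patient_id")
    plan_df = tumor[["density", "richness_extrapolated", "clonality"]].dropna()
    plan = [
        {"name": "tumor density vs richness", "method": "spearman",
         "x": "density", "y": "richness_extrapolated"},
        {"name": "tumor density vs clonality", "method": "spearman",
         "x": "density", "y": "clonality"},
        {"name": "tumor richness vs clonality", "method": "spearman",
         "x": "richness_extrapolated", "y": "clonality"},
    ]
    assoc = stats.association_table(stats.associate(plan_df, plan))
    RESULTS.mkdir(exist_ok=True)
    assoc.to_csv(RESULTS / "associations.csv", index=False, lineterminator="\n")
    print(assoc.to_string(index=False))

    wide = metrics.pivot_table(index="patient_id", columns="compartment", values="density")
    patients = manifest.patients
    df = (
        patients.merge(wide.add_suffix("_density"), left_on="patient_id", right_index=True)
        .merge(lec, on="patient_id", how="left")
    )
    results = []
    for var in ("PBMC_density", "ADJACENT_LUNG_density", "lung_enriched_clonality"):
        try:
            results.append(stats.survival_analysis(df, var))
        except ValueError as exc:
            print(f"{var}: skipped ({exc})")
    table = stats.survival_table(results)
    table.to_csv(RESULTS / "survival.csv", index=False, lineterminator="\n")
    print()
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
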