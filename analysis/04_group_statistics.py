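#!/usr/bin/env python
"""Normality-gated group comparisons and contractility correlations.

Merges the hemodynamic, hormone and HRV tables, runs the three-group
procedure (KS gate -> ANOVA/Bonferroni or Kruskal–Wallis/rank post hocs)
on every variable, and computes Spearman correlations between aortic peak
velocity (the contractility surrogate) and the HRV indices.
"""

import argparse
from pathlib import Path

import pandas as pd

from sepsishrv.config import PipelineConfig
from sepsishrv.stats import cohort_comparison_table, spearman_matrix

OUT = Path("results/analysis")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed)

    cohort = pd.read_csv(OUT / "cohort_hemodynamics.csv")
    hormones = pd.read_csv(OUT / "cohort_hormones.csv")
    hrv = pd.read_csv(OUT / "hrv_indices.csv")

    # hormones come from a per-group assayed subset; align by group order
    merged = cohort.merge(hrv.drop(columns=["group"]), on="animal_id")
    for g in merged["group"].unique():
        idx = merged.index[merged["group"] == g]
        sub = hormones[hormones["group"] == g].reset_index(drop=True)
        for col in sub.columns:
            if col in ("animal_id", "group", "truncated_fields"):
                continue
            merged.loc[idx[: len(sub)], col] = sub[col].to_numpy()

    comparisons = cohort_comparison_table(merged, gate=cfg.gate, alpha=cfg.alpha)
    comparisons.to_csv(OUT / "group_comparisons.csv", index=False)

    rho, p = spearman_matrix(
        merged, ["peak_velocity"], ["lf_power", "hf_power", "lf_hf"]
    )
    rho.to_csv(OUT / "spearman_rho.csv")
    p.to_csv(OUT / "spearman_p.csv")

    flagged = comparisons[
        comparisons.get("markers_sepsis_bad", "").fillna("") != ""
    ]["variable"].tolist()
    print(f"{len(comparisons)} variables compared; "
          f"bad-prognosis group flagged on: {flagged}")
    print("\nSpearman rho (peak velocity vs HRV):")
    print(rho.round(3).to_string())
    print("p-values:")
    print(p.round(4).to_string())


if __name__ == "__main__":
    main()
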