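#!/usr/bin/env python
"""Stroke volume, cardiac output and the prognosis split.

Back-solves each animal's VTI from its simulated stroke volume, then
recomputes SV = VTI x aortic area and CO = SV x HR from first principles
and applies the 0.93 m/s peak-velocity cutoff.  Prints the group means
next to the published rows they emulate.
"""

import argparse
from pathlib import Path

import pandas as pd

from sepsishrv.config import PipelineConfig
from sepsishrv.hemodynamics import aortic_area, hemodynamics_table

OUT = Path("results/analysis")

PUBLISHED_CO = {"sham": 103, "sepsis_good": 115, "sepsis_bad": 85}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)  # unused; kept for symmetry
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed)

    cohort = pd.read_csv(OUT / "cohort_hemodynamics.csv")
    area = aortic_area(cfg.aortic_diameter_mm)
    echo = pd.DataFrame({
        "animal_id": cohort["animal_id"],
        "group": cohort["group"],
        "vti_cm": cohort["stroke_volume"] / area,
        "pv_ms": cohort["peak_velocity"],
        "hr_bpm": cohort["heart_rate"],
    })
    hemo = hemodynamics_table(echo, cutoff=cfg.pv_cutoff,
                              diameter_mm=cfg.aortic_diameter_mm)
    hemo.to_csv(OUT / "hemodynamics.csv", index=False)

    print(f"aortic area ({cfg.aortic_diameter_mm} mm): {area:.5f} cm^2")
    co = hemo.groupby("group")["cardiac_output_ml_min"].mean()
    for g, published in PUBLISHED_CO.items():
        print(f"  {g}: CO {co[g]:.1f} ml/min (published {published})")
    septic = hemo[hemo["group"] != "sham"]
    n_good = (septic["prognosis"] == "good").sum()
    print(f"prognosis split among {len(septic)} septic survivors: "
          f"{n_good} good / {len(septic) - n_good} bad "
          f"({100 * n_good / len(septic):.0f} % good)")


if __name__ == "__main__":
    main()
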