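#!/usr/bin/env python
"""Per-animal HRV indices through the full signal chain.

For every animal in the simulated cohort: IPFM beat simulation with its
group's autonomic modulation profile, 1 kHz ECG rendering, R-peak
detection, ectopic editing, 10 Hz tachogram, smoothness-priors detrend,
and AR(16) spectral indices averaged over 3-min 50 %-overlap segments.
The group contrast built into the generator — elevated LF power and LF/HF
in good-prognosis sepsis — should be visible in the group medians printed
at the end.
"""

import argparse
from pathlib import Path

import pandas as pd

from sepsishrv.config import PipelineConfig
from sepsishrv.pipeline import DEFAULT_GROUP_MODULATION, _animal_hrv

OUT = Path("results/analysis")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed)

    cohort = pd.read_csv(OUT / "cohort_hemodynamics.csv")
    rows = []
    for i, row in cohort.iterrows():
        mod = DEFAULT_GROUP_MODULATION[row["group"]]
        idx, n_replaced = _animal_hrv(cfg, mod, seed=cfg.stage_seed(100 + i))
        idx.update(animal_id=row["animal_id"], group=row["group"],
                   n_ectopic_replaced=n_replaced)
        rows.append(idx)
    hrv = pd.DataFrame(rows)
    hrv.to_csv(OUT / "hrv_indices.csv", index=False)

    med = hrv.groupby("group")[["total_power", "lf_power", "hf_power",
                                "lf_hf"]].median().round(2)
    print(f"HRV indices for {len(hrv)} animals "
          f"({hrv['n_segments'].iloc[0]:.0f} segments each)")
    print(med.to_string())
    good, sham = med.loc["sepsis_good"], med.loc["sham"]
    print(f"\ngood-prognosis LF/HF {good['lf_hf']:.2f} vs sham "
          f"{sham['lf_hf']:.2f}: sympathetic predominance reproduced"
          if good["lf_hf"] > sham["lf_hf"] else "\nWARNING: LF/HF contrast absent")


if __name__ == "__main__":
    main()
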