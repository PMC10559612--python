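#!/usr/bin/env python
"""Who the clinical time is spent on: workload shares by age group and sex.

Runs 50 age-tracked trials per archetype (age attribution is the expensive
output, so it uses a reduced trial count) and writes the start-year share of
total clinical minutes by reporting age group and sex to
results/age_attribution.csv, printing the under-five and reproductive-age
female shares.
"""

from pathlib import Path

import pandas as pd

from phcworkload import (
    ScenarioConfig,
    SamplingConfig,
    load_region_parameters,
    run_scenario,
)

SEED = 2020
N_TRIALS = 50
ROOT = Path(__file__).resolve().parents[1]
PARAMS = ROOT / "results" / "params"


def main() -> None:
    frames = []
    for workbook in sorted(PARAMS.iterdir()):
        if not workbook.is_dir():
            continue
        region = load_region_parameters(workbook)
        cfg = ScenarioConfig(
            region=region,
            sampling=SamplingConfig(master_seed=SEED, n_trials=N_TRIALS),
            track_age=True,
        )
        by_age = run_scenario(cfg).by_age
        start = by_age[by_age.year == by_age.year.min()]
        shares = (
            start.groupby(["age_group", "sex"])["minutes"].mean()
            / start.groupby(["age_group", "sex"])["minutes"].mean().sum()
        ).rename("share").reset_index()
        shares.insert(0, "archetype", workbook.name)
        frames.append(shares)
        u5 = shares[shares.age_group.isin(["infants", "under_5"])]["share"].sum()
        fem_1549 = shares[
            shares.age_group.isin(["15-24", "25-34", "35-44", "45-54"])
            & (shares.sex == "female")
        ]["share"].sum()
        print(
            f"{workbook.name}: under-five share {u5:.1%}, "
            f"women 15-54 share {fem_1549:.1%}"
        )
    out = ROOT / "results" / "age_attribution.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
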