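"""Aggregate person-years into strata and bin PM2.5 into deciles.

Reads the cohort written by 01_simulate_cohort.py, collapses it to
estimation strata, computes person-year-weighted decile boundaries and
per-bin summaries, and reports how evenly the person-year mass splits
(the marginal bin probability P(X in i) = 1/K that stabilizes the weights).
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import dosebin as db

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = db.read_cohort_csv(str(SCRATCH / "cohort.csv"))
    strata = db.aggregate_person_years(cohort)
    binned, definition = db.assign_exposure_bins(strata, "pm25", n_bins=10)
    binned.to_csv(SCRATCH / "strata_binned.csv", index=False)
    definition.to_json(str(RESULTS / "pm25_bins.json"))

    total = strata["person_years"].sum()
    fractions = definition.bin_person_years / total
    print(f"{len(cohort)} rows -> {len(strata)} strata "
          f"({total:.0f} person-years, conserved: "
          f"{total == cohort['person_years'].sum()})")
    print("PM2.5 decile boundaries (ug/m3):",
          np.round(definition.boundaries, 2).tolist())
    print("per-bin person-year fractions:", np.round(fractions, 4).tolist())
    print(f"max deviation from 1/10: {np.abs(fractions - 0.1).max():.5f} "
          f"(stratum granularity {strata['person_years'].max() / total:.5f})")
    print("per-bin mean exposure:", np.round(definition.bin_mean_exposure, 2).tolist())


if __name__ == "__main__":
    main()
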