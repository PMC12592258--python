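#!/usr/bin/env python
"""Step 2 — simulate the four study scenarios with the calibrated model.

Monte Carlo cohorts of 10,000 virtual patients (log-normal 70 kg weight with
20% CV, 1:1 sex, genotype fixed per scenario) are run through the steady-state
engine under: non-null 240 mg QD (reference), null 240 mg QD, null 160 mg QD,
and null 240 mg every other day.  Writes the per-scenario exposure table and
patient-level metrics under results/.

Runs step 1 automatically if the calibrated model is missing.
"""

import runpy
from pathlib import Path

from lazdose.analysis import run_scenarios
from lazdose.calibration import CalibrationResult, load_targets

SEED = 2025
N = 10000
ROOT = Path(__file__).resolve().parents[1]
MODEL = ROOT / "results" / "calibrated_model.json"


def main() -> None:
    if not MODEL.exists():
        runpy.run_path(str(ROOT / "analysis" / "01_calibrate.py"), run_name="__main__")
    result = CalibrationResult.from_json(MODEL)
    targets = load_targets()

    report = run_scenarios(
        result.typical, n=N, seed=SEED,
        threshold=targets.threshold_mg_per_l,
        price_per_dosing_day=targets.price_per_dosing_day_usd,
    )
    out = ROOT / "results"
    report.to_csv(out / "exposure_table.csv")
    report.to_json(out / "exposure_table.json")
    report.long_values().to_csv(out / "patient_metrics_long.csv", index=False)

    print(f"simulated {N} patients per scenario (seed {SEED}):\n")
    print(report.table().to_string(index=False))
    print(f"\nwrote {out / 'exposure_table.csv'} and patient-level metrics")


if __name__ == "__main__":
    main()
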