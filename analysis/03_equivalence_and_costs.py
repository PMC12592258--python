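#!/usr/bin/env python
"""Step 3 — equivalence verdicts, threshold attainment, and annual drug cost.

Reads the scenario simulation from step 2 (running it if needed) and reports,
for each genotype-guided alternative regimen in GSTM1-null patients versus the
approved 240 mg QD dose in non-null patients:

* the geometric mean ratios for Ctrough and Caverage with the 0.80-1.25
  virtual-bioequivalence verdict and the one-sided "not >20% lower" criterion,
* the percentage of patients above the 0.0568 mg/L trough efficacy threshold,
* the yearly drug cost at $728 per dosing day and the saving vs daily dosing.

Writes results/equivalence_costs.json.
"""

import json
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

    doc = {"n": N, "seed": SEED, "threshold_mg_per_l": targets.threshold_mg_per_l,
           "comparisons": []}
    print(f"reference arm: GSTM1 non-null, 240 mg QD (n={N})\n")
    for (genotype, regimen), cmps in report.comparisons.items():
        cost = report.costs[(genotype, regimen)]
        frac = cmps["Ctrough"].fraction_above_threshold_pct
        entry = {
            "genotype": genotype,
            "regimen": regimen,
            "gmr_ctrough": round(cmps["Ctrough"].gmr, 2),
            "gmr_caverage": round(cmps["Caverage"].gmr, 2),
            "equivalent_ctrough": cmps["Ctrough"].equivalence_pass,
            "equivalent_caverage": cmps["Caverage"].equivalence_pass,
            "not_lower_ctrough": cmps["Ctrough"].not_lower_pass,
            "not_lower_caverage": cmps["Caverage"].not_lower_pass,
            "pct_ctrough_above_threshold": round(frac, 1),
            "annual_cost_usd": cost.annual_cost,
            "annual_savings_usd": cost.savings_vs_reference,
        }
        doc["comparisons"].append(entry)
        print(f"{genotype} {regimen}:")
        print(f"  GMR Ctrough  {entry['gmr_ctrough']:.2f}  "
              f"(0.80-1.25 {'pass' if entry['equivalent_ctrough'] else 'fail'}; "
              f"not->20%-lower {'pass' if entry['not_lower_ctrough'] else 'fail'})")
        print(f"  GMR Caverage {entry['gmr_caverage']:.2f}  "
              f"(0.80-1.25 {'pass' if entry['equivalent_caverage'] else 'fail'}; "
              f"not->20%-lower {'pass' if entry['not_lower_caverage'] else 'fail'})")
        print(f"  Ctrough > {targets.threshold_mg_per_l} mg/L: {entry['pct_ctrough_above_threshold']}%")
        print(f"  annual cost ${entry['annual_cost_usd']:,.0f} "
              f"(saves ${entry['annual_savings_usd']:,.0f}/year vs reference)\n")

    from lazdose.analysis import fraction_above

    doc["reference_pct_above_threshold"] = round(
        fraction_above(report.values[("non-null", "240QD")]["Ctrough"],
                       targets.threshold_mg_per_l), 1)
    print(f"reference arm Ctrough > threshold: {doc['reference_pct_above_threshold']}%")

    out = ROOT / "results" / "equivalence_costs.json"
    out.write_text(json.dumps(doc, indent=2) + "\n")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
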