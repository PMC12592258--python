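{
  "description": "Reference steady-state lazertinib exposure metrics by GSTM1 genotype and regimen (Monte Carlo simulation of the regulatory population-PK model; geometric means with arithmetic %CV), plus the proposed efficacy threshold.",
  "threshold_mg_per_l": 0.0568,
  "price_per_dosing_day_usd": 728.0,
  "scenarios": [
    {
      "genotype": "non-null",
      "regimen": "240QD",
      "ctrough_gm": 0.0962,
      "ctrough_cv_pct": 64.1,
      "caverage_gm": 0.174,
      "caverage_cv_pct": 42.5
    },
    {
      "genotype": "null",
      "regimen": "240QD",
      "ctrough_gm": 0.206,
      "ctrough_cv_pct": 56.2,
      "caverage_gm": 0.310,
      "caverage_cv_pct": 42.5
    },
    {
      "genotype": "null",
      "regimen": "160QD",
      "ctrough_gm": 0.138,
      "ctrough_cv_pct": 56.0,
      "caverage_gm": 0.207,
      "caverage_cv_pct": 42.5
    },
    {
      "genotype": "null",
      "regimen": "240QOD",
      "ctrough_gm": 0.0864,
      "ctrough_cv_pct": 64.0,
      "caverage_gm": 0.155,
      "caverage_cv_pct": 42.5
    }
  ]
}
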