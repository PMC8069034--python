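{
  "description": "Final population PK-PD parameter estimates for MEDI7836 (anti-IL13 IgG1-lambda-YTE) from the first-in-human single-ascending-dose study NCT02388347. Point estimates are population medians; ci95 are bootstrap (n=500) percentile intervals.",
  "units_note": "Rates 1/day, clearances L/day, volumes L (all apparent, /F), kin nM/day in the central reference space, kon 1/(nM*day). IIV reported as %CV of the log-normal random effect. The additive PK residual SD is on the ug/L mass scale (0.0546 ug/L = 3.64e-4 nM at 150 kDa); the PD residual is proportional on the natural-log scale.",
  "structural": {
    "ka": {"value": 0.156, "unit": "1/day", "ci95": [0.137, 0.183]},
    "cl_f": {"value": 0.441, "unit": "L/day", "ci95": [0.366, 0.587]},
    "v2_f": {"value": 2.83, "unit": "L", "ci95": [2.21, 4.06]},
    "q_f": {"value": 0.825, "unit": "L/day", "ci95": [0.638, 1.13]},
    "v3_f": {"value": 8.03, "unit": "L", "ci95": [6.82, 9.52]},
    "kin": {"value": 0.0173, "unit": "nM/day", "ci95": [0.0136, 0.0227]},
    "kout": {"value": 180.0, "unit": "1/day", "ci95": [143.0, 227.0]},
    "vcx_f": {"value": 13.6, "unit": "L", "ci95": [10.5, 16.7]},
    "fr": {"value": 0.0429, "unit": "fraction", "ci95": [0.0298, 0.0596]},
    "kon": {"value": 138.24, "unit": "1/(nM*day)", "fixed": true},
    "koff": {"value": 0.69, "unit": "1/day", "fixed": true},
    "ada_cl_effect": {"value": 0.717, "unit": "fraction", "ci95": [0.173, 1.55]}
  },
  "iiv_cv_percent": {
    "cl_f": {"value": 53.3, "ci95": [42.5, 64.8], "shrinkage_percent": 12.3},
    "v2_f": {"value": 72.7, "ci95": [44.4, 97.5], "shrinkage_percent": 17.8},
    "q_f": {"value": 69.6, "ci95": [19.7, 166.0], "shrinkage_percent": 28.6},
    "v3_f": {"value": 46.2, "ci95": [30.6, 65.0], "shrinkage_percent": 23.6},
    "kout": {"value": 57.1, "ci95": [38.2, 74.3], "shrinkage_percent": 17.6},
    "fr": {"value": 154.0, "ci95": [64.1, 295.0], "shrinkage_percent": 14.3}
  },
  "residual": {
    "pk_add_sd_ug_l": {"value": 0.0546, "ci95": [0.0131, 13.9]},
    "pk_prop_sd": {"value": 0.13, "ci95": [0.111, 0.361]},
    "pd_prop_sd": {"value": 0.069, "ci95": [0.0512, 0.0864]}
  }
}
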