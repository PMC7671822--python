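{
  "schema_version": 1,
  "description": "Base-case model inputs: UK NHS perspective, 2016 GBP, 15-year horizon, 3-month cycles, 3.5% annual discount.",
  "clinical": {
    "hf": {
      "trial_success": {"value": 0.928, "ci": [0.876, 0.979], "family": "beta"},
      "p_optimal_6mo": {"value": 0.809, "ci": [0.727, 0.891], "family": "beta"},
      "p_complication_6mo": {"value": 0.337, "ci": [0.239, 0.435], "family": "beta"},
      "explant_yr1": {"value": 0.044, "ci": [0.002, 0.087], "family": "beta"},
      "explant_yr2": {"value": 0.047, "ci": [0.002, 0.091], "family": "beta"},
      "explant_yr3plus": {"value": 0.032, "ci": [0.0, 0.158], "family": "beta"},
      "p_complication_late": {"value": 0.037, "ci": [0.006, 0.071], "family": "beta"}
    },
    "lf": {
      "trial_success": {"value": 0.880, "ci": [0.814, 0.947], "family": "beta"},
      "p_optimal_6mo": {"value": 0.544, "ci": [0.435, 0.652], "family": "beta"},
      "p_complication_6mo": {"value": 0.358, "ci": [0.254, 0.462], "family": "beta"},
      "explant_yr1": {"value": 0.111, "ci": [0.043, 0.180], "family": "beta"},
      "explant_yr2": {"value": 0.097, "ci": [0.029, 0.166], "family": "beta"},
      "explant_yr3plus": {"value": 0.032, "ci": [0.0, 0.158], "family": "beta"},
      "p_complication_late": {"value": 0.128, "ci": [0.068, 0.189], "family": "beta"}
    }
  },
  "arms": {
    "HF10": {
      "clinical": "hf",
      "cost_implant": {"value": 16648, "ci": [13116, 21421], "family": "gamma"},
      "cost_reimplant": null,
      "device_longevity_years": {"value": 10, "ci": [8, 25], "family": "gamma"}
    },
    "NRLF": {
      "clinical": "lf",
      "cost_implant": {"value": 11281, "ci": [8888, 14516], "family": "gamma"},
      "cost_reimplant": null,
      "device_longevity_years": {"value": 4, "ci": [2, 6], "family": "gamma"}
    },
    "RLF": {
      "clinical": "lf",
      "cost_implant": {"value": 17422, "ci": [13726, 22418], "family": "gamma"},
      "cost_reimplant": null,
      "device_longevity_years": {"value": 10, "ci": [8, 25], "family": "gamma"}
    }
  },
  "shared": {
    "p_optimal_cmm_6mo": {"value": 0.093, "ci": [0.084, 0.102], "family": "beta"},
    "annual_mortality": {"value": 0.0081, "ci": [0.007, 0.009], "family": "beta"},
    "p_reoperation": {"value": 0.05, "ci": [0.045, 0.055], "family": "beta"},
    "p_optimal_post_reop": {"value": 0.19, "ci": [0.171, 0.209], "family": "beta"},
    "cost_trial": {"value": 5281, "ci": [3441, 7931], "family": "gamma"},
    "cost_failed_trial_removal": {"value": 2140, "ci": [921, 3593], "family": "gamma"},
    "cost_explant": {"value": 2140, "ci": [0, 3015], "family": "gamma"},
    "cost_complication": {"value": 740, "ci": [241, 1869], "family": "gamma"},
    "cost_drug_cmm_6mo": {"value": 3167, "ci": [0, 8412], "family": "gamma"},
    "cost_nondrug_cmm_6mo": {"value": 956, "ci": [0, 1157], "family": "gamma"},
    "cost_drug_scs_6mo": {"value": 2012, "ci": [0, 8412], "family": "gamma"},
    "cost_nondrug_scs_6mo": {"value": 33, "ci": [0, 40], "family": "gamma"},
    "cost_reoperation": {"value": 0, "family": "fixed"},
    "discount_rate": {"value": 0.035, "family": "fixed"},
    "horizon_years": {"value": 15, "family": "fixed"},
    "cycle_length_years": {"value": 0.25, "family": "fixed"},
    "wtp_per_qaly": {"value": 20000, "family": "fixed"}
  },
  "utilities": {
    "u_opt_nc": {"value": 0.598, "ci": [0.538, 0.658], "family": "beta"},
    "u_opt_c": {"value": 0.528, "ci": [0.475, 0.581], "family": "beta"},
    "u_subopt_nc": {"value": 0.258, "ci": [0.232, 0.284], "family": "beta"},
    "u_subopt_c": {"value": 0.258, "ci": [0.232, 0.284], "family": "beta"},
    "u_no_relief": {"value": 0.168, "ci": [0.151, 0.185], "family": "beta"}
  }
}
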