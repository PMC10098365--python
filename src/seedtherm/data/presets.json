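{
  "populations": {
    "black_ar_1": {
      "comment": "Seedlot #1 black seeds, after-ripened (non-dormant state)",
      "params": {
        "T_base": 8.0, "theta_cold_50": 144.0, "sigma_theta": 35.0,
        "T_c_50": 35.0, "sigma_Tc": 2.5, "theta_warm": 99.0,
        "p_viable": 0.6, "er_lag_50": 1.0, "lag_multiplier_aba": 3.0
      },
      "recovery_design": {
        "temperatures": [10, 13, 16, 19, 22, 24, 28, 31, 34],
        "n_dishes": 3, "seeds_per_dish": 30, "scoring_days": 60
      }
    },
    "brown_1": {
      "comment": "Seedlot #1 brown seeds (non-dormant, low sharp ceiling)",
      "params": {
        "T_base": 10.0, "theta_cold_50": 150.0, "sigma_theta": 30.0,
        "T_c_50": 31.0, "sigma_Tc": 1.0, "theta_warm": 46.9,
        "p_viable": 0.6, "er_lag_50": 1.0, "lag_multiplier_aba": 3.0
      },
      "recovery_design": {
        "temperatures": [10, 13, 16, 19, 22, 24, 26, 28, 30],
        "n_dishes": 3, "seeds_per_dish": 30, "scoring_days": 60
      }
    },
    "seedlot_2": {
      "comment": "Seedlot #2 seed morphs (black and brown behave alike)",
      "params": {
        "T_base": 10.5, "theta_cold_50": 140.0, "sigma_theta": 15.0,
        "T_c_50": 33.5, "sigma_Tc": 2.0, "theta_warm": 140.0,
        "p_viable": 0.6, "er_lag_50": 1.0, "lag_multiplier_aba": 3.0
      },
      "recovery_design": {
        "temperatures": [13, 15, 17, 19, 21, 23, 26, 29, 32],
        "n_dishes": 3, "seeds_per_dish": 30, "scoring_days": 60
      }
    }
  },
  "dormancy_states": {
    "fh_black_1": {
      "comment": "Freshly harvested dormant black #1 seeds: layer fractions over viable seeds, chosen to reproduce the treatment G_max ladder 10/60/95 with a 0.95 viability ceiling",
      "base_population": "black_ar_1",
      "viability_ceiling": 0.95,
      "state": {
        "f_nd": 0.10526315789473684,
        "f_npd": 0.5263157894736842,
        "f_dpd": 0.3684210526315789
      },
      "rules": {
        "scarified_release": 0.7894736842105263,
        "flu_ga_increment": 0.05,
        "aba_half_saturation_um": 10.0
      }
    }
  }
}
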