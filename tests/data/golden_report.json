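{
  "version": "0.1.0",
  "seed": 2024,
  "stages": {
    "simulate": {
      "n_records": 840,
      "params": {
        "T_base": 8.0,
        "theta_cold_50": 144.0,
        "sigma_theta": 35.0,
        "T_c_50": 35.0,
        "sigma_Tc": 2.5,
        "theta_warm": 99.0,
        "p_viable": 0.6,
        "er_lag_50": 1.0,
        "lag_multiplier_aba": 3.0
      },
      "treatment_id": "water",
      "output": "simulated.csv"
    },
    "fit": {
      "T_base": 8.742626112473134,
      "theta_cold_50": 154.8753196801359,
      "sigma_theta": 48.946648479558036,
      "T_c_50": 34.95063466417258,
      "sigma_Tc": 2.780539897409316,
      "theta_warm": 103.66374934840466,
      "T_opt": 24.44227923598659,
      "g_max_estimate": 65.55555555555556,
      "sub_regressions": [
        {
          "percentile": 10.0,
          "slope": 0.00835343069675015,
          "intercept": -0.061551827438878826,
          "r2": 0.9417780374725053,
          "x_intercept": 7.368448925161392,
          "n_temperatures": 5,
          "theta_cold": 119.71129423376237
        },
        {
          "percentile": 20.0,
          "slope": 0.007647296708211558,
          "intercept": -0.06103594688134515,
          "r2": 0.985817239574743,
          "x_intercept": 7.9813755383396625,
          "n_temperatures": 5,
          "theta_cold": 130.76516292694834
        },
        {
          "percentile": 30.0,
          "slope": 0.006910944565076216,
          "intercept": -0.054847337425409794,
          "r2": 0.9915117379787686,
          "x_intercept": 7.936301168233277,
          "n_temperatures": 5,
          "theta_cold": 144.69802073849678
        },
        {
          "percentile": 40.0,
          "slope": 0.006488045994849721,
          "intercept": -0.0548779889849915,
          "r2": 0.9815036795825004,
          "x_intercept": 8.458323049582914,
          "n_temperatures": 5,
          "theta_cold": 154.12961017751886
        },
        {
          "percentile": 50.0,
          "slope": 0.005957935840530407,
          "intercept": -0.05208800545586071,
          "r2": 0.9491340800860013,
          "x_intercept": 8.742626112473134,
          "n_temperatures": 5,
          "theta_cold": 167.84336501196273
        },
        {
          "percentile": 60.0,
          "slope": 0.004037471496744165,
          "intercept": -0.023471402712804748,
          "r2": 0.9909995373911886,
          "x_intercept": 5.813391557496367,
          "n_temperatures": 3,
          "theta_cold": 247.67976710334784
        }
      ],
      "supra_regressions": [
        {
          "percentile": 10.0,
          "slope": -0.009582309582309578,
          "intercept": 0.362080262080262,
          "r2": 0.9945510026155189,
          "x_intercept": 37.7863247863248,
          "n_temperatures": 3,
          "T_c": 37.7863247863248
        },
        {
          "percentile": 20.0,
          "slope": -0.0097108378541986,
          "intercept": 0.3525755217882126,
          "r2": 0.984561299063844,
          "x_intercept": 36.3074254849979,
          "n_temperatures": 3,
          "T_c": 36.3074254849979
        },
        {
          "percentile": 30.0,
          "slope": -0.009496428085278355,
          "intercept": 0.33641066603070097,
          "r2": 0.9956065331919906,
          "x_intercept": 35.42496852603083,
          "n_temperatures": 3,
          "T_c": 35.42496852603083
        },
        {
          "percentile": 40.0,
          "slope": -0.010174367916303396,
          "intercept": 0.3466521360069746,
          "r2": 0.9981508517954987,
          "x_intercept": 34.071122536418166,
          "n_temperatures": 3,
          "T_c": 34.071122536418166
        }
      ],
      "diagnostics": {
        "per_temperature_gmax": {
          "13.0": 65.55555555555556,
          "16.0": 51.111111111111114,
          "19.0": 50.0,
          "22.0": 62.22222222222223,
          "24.0": 61.111111111111114,
          "28.0": 51.111111111111114,
          "31.0": 45.55555555555555
        },
        "reference_percentile": 50.0,
        "percentiles": [
          10.0,
          20.0,
          30.0,
          40.0,
          50.0,
          60.0
        ],
        "theta_probit": {
          "slope": 48.946648479558036,
          "r2": 0.8476320447929571,
          "n": 6,
          "sd_of_estimates": 45.807955237501794
        },
        "sub_dropped": [],
        "event": "er",
        "tc_probit": {
          "slope": -2.780539897409316,
          "r2": 0.993676749715254,
          "n": 4,
          "sd_of_estimates": 1.5593415922287017
        },
        "supra_dropped": [
          [
            50.0,
            "too few temperatures"
          ],
          [
            60.0,
            "too few temperatures"
          ]
        ],
        "t_opt_reference_lines": NaN
      }
    },
    "dormancy": {
      "f_nd": 0.1111111111111111,
      "f_npd": 0.5555555555555556,
      "f_dpd": 0.33333333333333337,
      "viable_fraction": 0.9,
      "of_all_seeds": {
        "f_nd": 0.09999999999999999,
        "f_npd": 0.5,
        "f_dpd": 0.30000000000000004,
        "non_viable": 0.09999999999999998
      }
    }
  }
}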