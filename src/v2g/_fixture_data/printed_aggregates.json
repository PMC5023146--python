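{
  "table1": {
    "note": "printed Mean +/- SD row; the dEF entry (-11.1 +/- 4.4) matches Group 2 only and is transcribed as printed, not corrected",
    "mean": {"age": 40.4, "EDV_pre": 387.7, "ESV_pre": 228.4, "EF_pre": 42.7,
             "EDV_post": 278.0, "ESV_post": 193.8, "EF_post": 31.4, "dEF": -11.1},
    "sd": {"age": 16.6, "EDV_pre": 154.8, "ESV_pre": 121.3, "EF_pre": 8.0,
           "EDV_post": 85.8, "ESV_post": 82.6, "EF_post": 9.9, "dEF": 4.4}
  },
  "table2": {
    "ave": {"1G-BF": 7.323, "1G-BE": 84.70, "2G-BF": 7.17, "2G-EF": 43.10,
            "2G-BE": 108.41, "2G-EE": 28.89}
  },
  "table3": {
    "ave": {"1G-BF": 0.062, "1G-BE": 0.434, "2G-BF": 0.048, "2G-EF": 0.425,
            "2G-BE": 0.606, "2G-EE": 0.164}
  },
  "table6": {
    "group1_mean": {"dEF": 1.34, "WT": 0.45, "C-cur": 0.48, "L-cur": 1.40,
                    "EDV": 302.3, "Stress": 82.9, "Strain": 0.59},
    "group1_sd": {"dEF": 3.9, "WT": 0.08, "C-cur": 0.07, "L-cur": 0.48,
                  "EDV": 93.7, "Stress": 27.5, "Strain": 0.09},
    "group2_mean": {"dEF": -11.1, "WT": 0.53, "C-cur": 0.57, "L-cur": 1.13,
                    "EDV": 387.4, "Stress": 133.9, "Strain": 0.62},
    "group2_sd": {"dEF": 4.4, "WT": 0.14, "C-cur": 0.34, "L-cur": 0.38,
                  "EDV": 154.8, "Stress": 31.4, "Strain": 0.14},
    "r_vs_dEF": {"WT": -0.313, "C-cur": 0.012, "L-cur": 0.433, "EDV": -0.60,
                 "Stress": -0.608, "Strain": 0.033},
    "p_vs_dEF": {"WT": 0.239, "C-cur": 0.965, "L-cur": 0.094, "EDV": 0.015,
                 "Stress": 0.012, "Strain": 0.903}
  }
}
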