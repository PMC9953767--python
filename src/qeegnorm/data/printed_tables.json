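{
  "description": "Published normative reference values for the 37-subject healthy cohort. cohort_logps: whole-cohort logPS mean/SEM per lobe, band and hemisphere with symmetric-lobe p values (* = Wilcoxon signed-rank, otherwise paired t). group_logps: logPS group means/SEM per age group. group_coherence: band-coherence group means per region (lobe or hemisphere) and age group. Age groups: <20 (n=7), 20-50 (n=25), >50 (n=5).",
  "age_group_n": {"<20": 7, "20-50": 25, ">50": 5},
  "cohort_logps": {
    "F":  {"delta": {"L": [1.24, 0.05], "R": [1.26, 0.06], "p": 0.379, "test": "t"},
           "theta": {"L": [0.72, 0.05], "R": [0.72, 0.04], "p": 0.854, "test": "t"},
           "alpha": {"L": [0.90, 0.06], "R": [0.91, 0.06], "p": 0.424, "test": "wilcoxon"},
           "beta":  {"L": [0.85, 0.05], "R": [0.89, 0.05], "p": 0.068, "test": "t"}},
    "PO": {"delta": {"L": [1.18, 0.05], "R": [1.19, 0.05], "p": 0.456, "test": "t"},
           "theta": {"L": [0.85, 0.06], "R": [0.85, 0.06], "p": 0.556, "test": "t"},
           "alpha": {"L": [1.52, 0.10], "R": [1.53, 0.10], "p": 0.400, "test": "t"},
           "beta":  {"L": [1.02, 0.05], "R": [0.99, 0.05], "p": 0.291, "test": "wilcoxon"}},
    "T":  {"delta": {"L": [1.31, 0.06], "R": [1.33, 0.06], "p": 0.490, "test": "t"},
           "theta": {"L": [0.84, 0.06], "R": [0.80, 0.06], "p": 0.084, "test": "t"},
           "alpha": {"L": [1.28, 0.08], "R": [1.27, 0.09], "p": 0.526, "test": "wilcoxon"},
           "beta":  {"L": [1.07, 0.05], "R": [1.02, 0.05], "p": 0.161, "test": "t"}}
  },
  "group_logps": {
    "F": {
      "<20":   {"delta": {"L": [1.64, 0.11], "R": [1.67, 0.13]},
                "alpha": {"L": [1.21, 0.07], "R": [1.30, 0.12]},
                "theta": {"L": [1.10, 0.05], "R": [1.09, 0.09]},
                "beta":  {"L": [0.90, 0.03], "R": [0.98, 0.05]}},
      "20-50": {"delta": {"L": [1.16, 0.05], "R": [1.18, 0.06]},
                "beta":  {"L": [0.81, 0.07], "R": [0.86, 0.06]},
                "alpha": {"L": [0.77, 0.07], "R": [0.77, 0.06]},
                "theta": {"L": [0.60, 0.03], "R": [0.63, 0.04]}},
      ">50":   {"delta": {"L": [1.11, 0.11], "R": [1.08, 0.05]},
                "alpha": {"L": [1.09, 0.11], "R": [1.06, 0.14]},
                "beta":  {"L": [0.96, 0.11], "R": [0.90, 0.09]},
                "theta": {"L": [0.78, 0.18], "R": [0.68, 0.12]}}
    },
    "PO": {
      "<20":   {"alpha": {"L": [2.07, 0.11], "R": [2.15, 0.10]},
                "delta": {"L": [1.57, 0.09], "R": [1.56, 0.09]},
                "theta": {"L": [1.28, 0.12], "R": [1.27, 0.11]},
                "beta":  {"L": [1.12, 0.07], "R": [1.14, 0.07]}},
      "20-50": {"alpha": {"L": [1.35, 0.12], "R": [1.35, 0.11]},
                "delta": {"L": [1.10, 0.05], "R": [1.11, 0.05]},
                "beta":  {"L": [0.98, 0.07], "R": [0.95, 0.07]},
                "theta": {"L": [0.73, 0.06], "R": [0.72, 0.06]}},
      ">50":   {"alpha": {"L": [1.57, 0.22], "R": [1.58, 0.25]},
                "beta":  {"L": [1.13, 0.09], "R": [1.00, 0.15]},
                "delta": {"L": [1.00, 0.11], "R": [1.05, 0.09]},
                "theta": {"L": [0.87, 0.04], "R": [0.88, 0.05]}}
    },
    "T": {
      "<20":   {"alpha": {"L": [1.79, 0.07], "R": [1.93, 0.14]},
                "delta": {"L": [1.71, 0.07], "R": [1.83, 0.06]},
                "beta":  {"L": [1.27, 0.05], "R": [1.24, 0.08]},
                "theta": {"L": [1.27, 0.10], "R": [1.28, 0.12]}},
      "20-50": {"delta": {"L": [1.20, 0.05], "R": [1.21, 0.06]},
                "alpha": {"L": [1.11, 0.09], "R": [1.06, 0.09]},
                "beta":  {"L": [1.00, 0.06], "R": [0.96, 0.07]},
                "theta": {"L": [0.71, 0.05], "R": [0.66, 0.06]}},
      ">50":   {"alpha": {"L": [1.41, 0.14], "R": [1.36, 0.12]},
                "delta": {"L": [1.29, 0.19], "R": [1.22, 0.23]},
                "beta":  {"L": [1.15, 0.11], "R": [0.95, 0.10]},
                "theta": {"L": [0.87, 0.12], "R": [0.83, 0.15]}}
    }
  },
  "group_coherence": {
    "H": {
      "<20":   {"L": {"alpha": 0.1871, "delta": 0.1792, "theta": 0.1690, "beta": 0.1135},
                "R": {"alpha": 0.2020, "delta": 0.1745, "theta": 0.1692, "beta": 0.1261}},
      "20-50": {"L": {"delta": 0.2062, "theta": 0.1668, "alpha": 0.1376, "beta": 0.1041},
                "R": {"delta": 0.201, "theta": 0.169, "alpha": 0.145, "beta": 0.104}},
      ">50":   {"L": {"alpha": 0.2004, "delta": 0.1803, "theta": 0.1734, "beta": 0.1217},
                "R": {"alpha": 0.2232, "delta": 0.1890, "theta": 0.1854, "beta": 0.1351}}
    },
    "F": {
      "<20":   {"L": {"delta": 0.2711, "theta": 0.2276, "alpha": 0.1863, "beta": 0.1630},
                "R": {"delta": 0.2878, "theta": 0.2328, "alpha": 0.1716, "beta": 0.1581}},
      "20-50": {"L": {"delta": 0.2654, "theta": 0.2100, "alpha": 0.1722, "beta": 0.1348},
                "R": {"delta": 0.2486, "theta": 0.205, "alpha": 0.1646, "beta": 0.1283}},
      ">50":   {"L": {"delta": 0.294, "theta": 0.2366, "alpha": 0.1679, "beta": 0.1575},
                "R": {"delta": 0.2544, "theta": 0.1986, "alpha": 0.1706, "beta": 0.1532}}
    },
    "PO": {
      "<20":   {"L": {"alpha": 0.2880, "theta": 0.2331, "beta": 0.1953, "delta": 0.1910},
                "R": {"alpha": 0.1948, "theta": 0.1738, "delta": 0.1697, "beta": 0.1314}},
      "20-50": {"L": {"alpha": 0.2020, "theta": 0.1760, "delta": 0.1534, "beta": 0.1204},
                "R": {"alpha": 0.2883, "theta": 0.2266, "beta": 0.2026, "delta": 0.1827}},
      ">50":   {"L": {"alpha": 0.2041, "theta": 0.1821, "delta": 0.1731, "beta": 0.1442},
                "R": {"alpha": 0.2658, "theta": 0.2376, "delta": 0.1856, "beta": 0.1376}}
    },
    "T": {
      "<20":   {"L": {"alpha": 0.2140, "delta": 0.1686, "theta": 0.154, "beta": 0.0976},
                "R": {"delta": 0.2238, "alpha": 0.1940, "theta": 0.1907, "beta": 0.1265}},
      "20-50": {"L": {"alpha": 0.2596, "theta": 0.2110, "delta": 0.1870, "beta": 0.1492},
                "R": {"alpha": 0.3120, "theta": 0.2110, "beta": 0.1924, "delta": 0.1647}},
      ">50":   {"L": {"delta": 0.2236, "alpha": 0.2117, "theta": 0.2001, "beta": 0.131},
                "R": {"alpha": 0.3330, "theta": 0.2644, "delta": 0.2314, "beta": 0.172}}
    }
  }
}
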