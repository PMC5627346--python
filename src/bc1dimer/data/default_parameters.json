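{
  "rate_constants": {
    "kfQp0,1": {"value": 2.38e3, "unit": "1/s"},
    "kfQp1,2": {"value": 1.26e3, "unit": "1/s"},
    "kfQp2,3": {"value": 3.15e3, "unit": "1/s"},
    "kfQp3,4": {"value": 2.27e3, "unit": "1/s"},
    "kfQp4,5": {"value": 4.14e0, "unit": "1/s"},
    "bAAr":    {"value": 3.44e2, "unit": "1"},
    "bAAf":    {"value": 5.00e0, "unit": "1"},
    "kfQn2,0": {"value": 9.19e9, "unit": "1/s"},
    "kfQn3,1": {"value": 9.21e9, "unit": "1/s"},
    "kfQn4,2": {"value": 6.98e3, "unit": "1/s"},
    "kfQn5,3": {"value": 1.13e4, "unit": "1/s"}
  },
  "binding_constants": {
    "Kc3+":       {"value": 1.11e-6, "unit": "M"},
    "Kc2+":       {"value": 2.49e-6, "unit": "M"},
    "Kc3+Mg2+":   {"value": 1.14e-5, "unit": "M"},
    "Kc2+Mg2+":   {"value": 1.15e-5, "unit": "M"},
    "KDQH2Qp":    {"value": 2.76e-6, "unit": "M"},
    "KDQQp":      {"value": 3.77e0,  "unit": "M"},
    "KDQQn":      {"value": 1.00e2,  "unit": "M"},
    "KDQH2Qn":    {"value": 1.00e0,  "unit": "M"},
    "KQ2H2Qp":    {"value": 7.29e-6, "unit": "M"},
    "KQ2Qp":      {"value": 1.57e0,  "unit": "M"},
    "KQ2Qn":      {"value": 2.24e1,  "unit": "M"},
    "KQ2H2Qn":    {"value": 1.00e0,  "unit": "M"},
    "KNBHQp":     {"value": 1.23e-5, "unit": "M"},
    "KNBQp":      {"value": 1.00e0,  "unit": "M"},
    "KNBQn":      {"value": 3.41e0,  "unit": "M"},
    "KNBHQn":     {"value": 2.42e-1, "unit": "M"},
    "KQH2mixQp":  {"value": 2.59e-8, "unit": "M"},
    "KQmixQp":    {"value": 1.00e0,  "unit": "M"},
    "KQmixQn":    {"value": 1.00e0,  "unit": "M"},
    "KQH2mixQn":  {"value": 1.00e-2, "unit": "M"},
    "KQ10H2Qp":   {"value": 1.00e-3, "unit": "M"},
    "KQ10Qp":     {"value": 1.00e-3, "unit": "M"},
    "KQ10Qn":     {"value": 1.00e-3, "unit": "M"},
    "KQ10H2Qn":   {"value": 1.00e-5, "unit": "M"}
  },
  "thermodynamic": {
    "dGbHbLCoulomb": {"value": 11.6, "unit": "kJ/mol"},
    "dGbLbLCoulomb": {"value": 5.3,  "unit": "kJ/mol"},
    "KSQ10":         {"value": 2.28e-15, "unit": "1"},
    "KSQanalog":     {"value": 9.34e-9,  "unit": "1"}
  },
  "initial_percent_oxidized": {
    "speck_margoliash":  {"value": 1.53, "unit": "%"},
    "brandt_okun":       {"value": 5.01, "unit": "%"},
    "esposti_lenaz":     {"value": 2.30, "unit": "%"},
    "kubota":            {"value": 0.32, "unit": "%"},
    "rottenberg":        {"value": 0.06, "unit": "%"},
    "covian_trumpower":  {"value": 2.59, "unit": "%"}
  },
  "fixed": {
    "Em_bL":    {"value": -60.0,  "unit": "mV"},
    "Em_bH":    {"value": 80.0,   "unit": "mV"},
    "Em_SQn":   {"value": 90.0,   "unit": "mV"},
    "Em_c":     {"value": 260.0,  "unit": "mV"},
    "Em_O2":    {"value": -160.0, "unit": "mV"},
    "Em_pool_Q10": {"value": 90.0, "unit": "mV"},
    "Em_pool_DQ":  {"value": 90.0, "unit": "mV"},
    "Em_pool_Q2":  {"value": 90.0, "unit": "mV"},
    "Em_pool_NB":  {"value": 90.0, "unit": "mV"},
    "Em_pool_mix": {"value": 90.0, "unit": "mV"},
    "k_O2":     {"value": 1.0e14, "unit": "1/M/s"},
    "depth_SQp": {"value": 0.0,  "unit": "1"},
    "depth_bL":  {"value": 0.0,  "unit": "1"},
    "depth_bH":  {"value": 0.5,  "unit": "1"},
    "depth_SQn": {"value": 1.0,  "unit": "1"}
  }
}
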