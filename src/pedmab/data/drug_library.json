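{
  "bevacizumab": {
    "mw_kda": 149.0,
    "sigma_v": 0.99,
    "sigma_l": 0.63,
    "kdeg_healthy": 12400.0,
    "kdeg_patient": 12400.0,
    "kon_fcrn": 8000.0,
    "koff_fcrn": 500.0,
    "tmdd_enabled": true,
    "tmdd_healthy": {
      "kon_t": 30.0,
      "koff_t": 0.006,
      "kint": 1.0,
      "ksyn": 3.4e-07,
      "kdeg_t": 0.173,
      "baseline_conc": 1.96e-06
    },
    "tmdd_patient": {
      "kon_t": 30.0,
      "koff_t": 0.006,
      "kint": 1.0,
      "ksyn": 6.7e-07,
      "kdeg_t": 0.173,
      "baseline_conc": 3.86e-06
    }
  },
  "infliximab": {
    "mw_kda": 149.1,
    "sigma_v": 0.99,
    "sigma_l": 0.60,
    "kdeg_healthy": 13400.0,
    "kdeg_patient": 20000.0,
    "kon_fcrn": 8000.0,
    "koff_fcrn": 500.0,
    "tmdd_enabled": false,
    "tmdd_healthy": null,
    "tmdd_patient": null
  },
  "atezolizumab": {
    "mw_kda": 145.0,
    "sigma_v": 0.99,
    "sigma_l": 0.29,
    "kdeg_healthy": 18000.0,
    "kdeg_patient": 18000.0,
    "kon_fcrn": 8000.0,
    "koff_fcrn": 500.0,
    "tmdd_enabled": false,
    "tmdd_healthy": null,
    "tmdd_patient": null
  }
}
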