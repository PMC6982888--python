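{
  "description": "Reference DLS characterization of egg-PC SUVs dispersed in 155 mM sodium salt solutions: bimodal intensity-weighted size distribution (nm, with SD and % intensity), polydispersity index, and zeta potential (mV). Documentation metadata only; justifies the thin-double-layer f(ka)=1.5 treatment.",
  "NaCl": {
    "size_modes_nm": [{"size": 215.5, "sd": 25.86, "intensity_pct": 85}, {"size": 50.70, "sd": 5.46, "intensity_pct": 15}],
    "pdi": 0.404,
    "zeta_mV": -5.73
  },
  "NaBr": {
    "size_modes_nm": [{"size": 198.7, "sd": 18.78, "intensity_pct": 94.7}, {"size": 30.34, "sd": 2.23, "intensity_pct": 5.3}],
    "pdi": 0.431,
    "zeta_mV": -6.33
  },
  "NaNO3": {
    "size_modes_nm": [{"size": 189.6, "sd": 19.85, "intensity_pct": 93.9}, {"size": 30.04, "sd": 2.19, "intensity_pct": 6.1}],
    "pdi": 0.532,
    "zeta_mV": -8.43
  },
  "NaI": {
    "size_modes_nm": [{"size": 163.0, "sd": 46.55, "intensity_pct": 88.8}, {"size": 38.29, "sd": 6.62, "intensity_pct": 11.2}],
    "pdi": 0.281,
    "zeta_mV": -10.27
  }
}
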