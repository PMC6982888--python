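{
  "NaCl": {"K_ANa": 0.230, "K_AH": 717.0, "K_BOH": 3.35e9, "K_BX": 0.076},
  "NaBr": {"K_ANa": 0.197, "K_AH": 264.0, "K_BOH": 3.54e9, "K_BX": 0.133},
  "NaNO3": {"K_ANa": 0.151, "K_AH": 47.0, "K_BOH": 5.99e9, "K_BX": 0.185},
  "NaI": {"K_ANa": 0.112, "K_AH": 13.0, "K_BOH": 1.73e10, "K_BX": 0.361}
}
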