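{
  "version": 1,
  "v_rest": -65.0,
  "trunk_lambda_target": 1009.0,
  "plateau_threshold": 1250.0,
  "geometry": {
    "soma": {"length": 35.0, "diameter": 35.0, "n": 1},
    "hillock": {"length": 20.0, "diameter": 3.5, "n": 2},
    "ais": {"length": 35.0, "diameter": 1.75, "n": 3},
    "basal": {"length": 300.0, "diameter": 10.0, "n": 10},
    "trunk": {"dx": 10.0},
    "tuft": {"length": 900.0, "diameter": 5.0, "n": 1}
  },
  "passive": {
    "cm": 1.0,
    "tuft_cm": 1.75,
    "ra": 150.0,
    "trunk_ra": 100.0,
    "trunk_rm": 15.0,
    "soma_rm": 15.0,
    "axon_rm": 15.0,
    "basal_rm": 15.0,
    "tuft_rm": 40.0
  },
  "densities": {
    "soma_nat": 300.0,
    "soma_nap": 0.25,
    "soma_kfast": 100.0,
    "soma_kslow": 150.0,
    "soma_km": 3.0,
    "hillock_nat": 500.0,
    "ais_nat": 1000.0,
    "basal_hcn": 4.0
  },
  "profiles": {
    "nat": {"anchor": 120.0, "zero_at": 1400.0},
    "kfast": {"anchor": 60.0, "decay_length": 80.0},
    "kslow": {"anchor": 120.0, "decay_length": 80.0, "floor": 2.0},
    "hcn": {"proximal": 2.0}
  },
  "tuft": {
    "nat": 2.0,
    "kfast": 0.1,
    "kslow": 0.1,
    "hcn": 2.0,
    "ca_total": 0.45,
    "hva_fraction": 0.1,
    "kca": 0.5,
    "pool": {"tau": 40.0, "phi": 0.002, "rest": 0.0001, "ca_o": 2.0}
  },
  "trunk_channel_params": {
    "Nat": {"h_shift": 10.0}
  },
  "channel_params": {
    "CaLVA": {"vshift": -12.0, "m_slope": 2.5, "rate_scale": 0.15, "h_shift": 40.0},
    "KCa": {"ca_half": 0.001, "hill": 4.8, "tau": 1.0}
  }
}
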