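{
  "version": 1,
  "units": {"chi_m": "A m^2 kg^-1 T^-1", "rho": "kg m^-3", "chi_v": "dimensionless"},
  "minerals": {
    "ferrihydrite": {"chi_m": [0.25, 2.1], "rho": [1200, 1200], "chi_v": [3.8e-4, 32e-4]},
    "magnetite": {"chi_m": [230, 950], "rho": [5180, 5180], "chi_v": [1.5, 6.2]},
    "maghemite": {"chi_m": [180, 530], "rho": [4860, 4860], "chi_v": [1.1, 3.2]},
    "hematite": {"chi_m": [0.10, 3.0], "rho": [5260, 5260], "chi_v": [6.6e-4, 200e-4]},
    "goethite": {"chi_m": [0.37, 4.8], "rho": [3300, 4300], "chi_v": [1.5e-3, 26e-3]}
  }
}
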