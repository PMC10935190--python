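# Simulation config for `silage-scan simulate`.
# Two seasons using the built-in presets, default three-instrument set.
seed: 42
seasons:
  - preset: "2021"
  - preset: "2022"
# instruments:                 # optional override; defaults shown
#   - instrument_id: 1
#     noise_sd: 0.004
#   - instrument_id: 2
#     wavelength_shift: 0.4
#     gain: 0.995
#     baseline_offset: 0.002
#     noise_sd: 0.004
#     em_response_offset: -1.5
#   - instrument_id: 3
#     wavelength_shift: 3.0
#     gain: 1.03
#     baseline_offset: 0.01
#     noise_sd: 0.004
#     em_response_gain: 0.96
#     em_response_offset: 4.5
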