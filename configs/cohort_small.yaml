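# Small synthetic cohort for the end-to-end pipeline run.
# Remaining generator parameters use the package defaults
# (17 networks, 80 parcels, canonical LH-RH offsets).
n_participants: 8
n_timepoints: 120
behavior:
  target_network: ContB
  effect_r: 0.4
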