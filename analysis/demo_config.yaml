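# Bundled demo study: 40 patients, one slide each, with a planted
# prognostic effect on invasive-band nucleus size (see melaband.synthetic).
simulation:
  n_patients: 40
  beta_invasive_size: 0.8   # log-hazard per sd of the latent morphology score
  size_shift_scale_um2: 6.0
  censoring_rate: 0.3
seed: 11
resolution_um: 10.0
bootstrap_B: 300
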