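{
 "name": "DCN",
 "kind": "cohort",
 "description": "Dorsal cochlear nucleus: serial block-face SEM, 384 slices at 8.5 x 8.5 x 100 nm (strongly anisotropic).",
 "spacing_nm": {"dx_nm": 8.5, "dy_nm": 8.5, "dz_nm": 100.0},
 "seed": 0,
 "jitter_amplitude_vox": 0,
 "groups": {
  "presynaptic": {
   "n": 85,
   "target_mean_um3": 0.375,
   "target_sem_um3": 0.03,
   "aspect_range": [1.0, 1.6],
   "components": [{"weight": 1.0, "mean_um3": 0.375, "sd_um3": null}]
  },
  "postsynaptic": {
   "n": 32,
   "target_mean_um3": 1.357,
   "target_sem_um3": 0.182,
   "aspect_range": [2.5, 6.0],
   "components": [{"weight": 1.0, "mean_um3": 1.357, "sd_um3": null}]
  }
 }
}
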