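{
 "name": "NA",
 "kind": "cohort",
 "description": "Nucleus accumbens: FIB-SEM, 562 slices, isotropic 4 nm voxels.",
 "spacing_nm": {"dx_nm": 4.0, "dy_nm": 4.0, "dz_nm": 4.0},
 "seed": 0,
 "jitter_amplitude_vox": 0,
 "groups": {
  "presynaptic": {
   "n": 67,
   "target_mean_um3": 0.05,
   "target_sem_um3": 0.004,
   "aspect_range": [1.0, 1.6],
   "components": [{"weight": 1.0, "mean_um3": 0.05, "sd_um3": null}]
  },
  "postsynaptic": {
   "n": 56,
   "target_mean_um3": 0.195,
   "target_sem_um3": 0.018,
   "aspect_range": [2.5, 6.0],
   "components": [{"weight": 1.0, "mean_um3": 0.195, "sd_um3": null}]
  }
 }
}
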