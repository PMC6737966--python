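{
 "name": "CA1",
 "kind": "cohort",
 "description": "Hippocampal CA1: FIB-SEM, 5080 slices, isotropic 8 nm voxels.",
 "spacing_nm": {"dx_nm": 8.0, "dy_nm": 8.0, "dz_nm": 8.0},
 "seed": 0,
 "jitter_amplitude_vox": 0,
 "groups": {
  "presynaptic": {
   "n": 200,
   "target_mean_um3": 0.043,
   "target_sem_um3": 0.002,
   "aspect_range": [1.0, 1.6],
   "components": [{"weight": 1.0, "mean_um3": 0.043, "sd_um3": null}]
  },
  "postsynaptic": {
   "n": 50,
   "target_mean_um3": 0.158,
   "target_sem_um3": 0.017,
   "aspect_range": [2.5, 6.0],
   "components": [{"weight": 1.0, "mean_um3": 0.158, "sd_um3": null}]
  }
 }
}
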