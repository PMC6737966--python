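{
 "name": "cortex",
 "kind": "cohort",
 "description": "Somatosensory cortex (layer V/VI): 1850 slices at 6 x 6 x 30 nm. The postsynaptic group is a three-component log-normal mixture: one subpopulation in the NA/CA1 size range and two subpopulations 3-10x larger; component means are chosen so the mixture mean equals the printed group mean (0.5*0.18 + 0.3*1.0 + 0.2*2.5 = 0.89).",
 "spacing_nm": {"dx_nm": 6.0, "dy_nm": 6.0, "dz_nm": 30.0},
 "seed": 0,
 "jitter_amplitude_vox": 0,
 "groups": {
  "presynaptic": {
   "n": 324,
   "target_mean_um3": 0.056,
   "target_sem_um3": 0.002,
   "aspect_range": [1.0, 1.6],
   "components": [{"weight": 1.0, "mean_um3": 0.056, "sd_um3": null}]
  },
  "postsynaptic": {
   "n": 55,
   "target_mean_um3": 0.89,
   "target_sem_um3": 0.124,
   "aspect_range": [2.5, 6.0],
   "components": [
    {"weight": 0.5, "mean_um3": 0.18, "sd_um3": 0.054},
    {"weight": 0.3, "mean_um3": 1.0, "sd_um3": 0.3},
    {"weight": 0.2, "mean_um3": 2.5, "sd_um3": 0.75}
   ]
  }
 }
}
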