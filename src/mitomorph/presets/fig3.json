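{
 "name": "fig3",
 "kind": "fig3_scene",
 "description": "One cortical dendrite contacted by four presynaptic boutons, with a single dendritic mitochondrion spanning all four synapses.",
 "spacing_nm": {"dx_nm": 6.0, "dy_nm": 6.0, "dz_nm": 30.0},
 "seed": 0,
 "boutons": 4,
 "extent_fraction": 1.0
}
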