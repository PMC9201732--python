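group,n,effective,markedly_effective,ineffective,complication_deep_vein_thrombosis,complication_screw_detachment,complication_fixation_rupture,sensory_block_h_mean,sensory_block_h_sd,motor_block_h_mean,motor_block_h_sd
experimental,25,13,10,2,2,0,0,7.53,1.47,5.45,1.36
control,25,10,10,5,2,1,1,3.38,1.26,3.02,1.31
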