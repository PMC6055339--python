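patient,presenting_cobb,manual_sim_cobb,manual_reduction_pct,therapist_force,manual_stiffness_index
P1,45,42,7,31,10
P2,25,21,14,33,10
P3,40,27,31,31,3
P4,33,25,23,28,4
P5,36,32,13,28,6
P6,23,16,31,23,3
P7,42,35,17,25,4
P8,36,27,26,25,3
P9,39,37,7,26,10
P10,28,10,64,55,3
P11,25,13,48,29,2
P12,37,31,18,33,5
P13,45,26,43,42,2
P14,11,5,53,31,5
P15,30,26,13,34,9
P16,31,27,13,28,7
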