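patient,presenting_cobb,actual_self_cobb,actual_self_reduction_pct,sim_self_cobb,sim_self_reduction_pct,apex_reaction_force,self_stiffness_index
P1,45,30,33,35,22,68,7
P2,25,19,24,21,17,27,6
P3,40,25,37,27,33,29,2
P4,33,23,29,24,27,22,2
P5,36,23,35,31,15,64,12
P6,23,16,29,12,47,8,1
P7,42,39,7,42,2,16,21
P8,36,17,53,27,27,52,5
P9,39,26,34,32,19,77,10
P10,28,22,19,25,11,24,8
P11,25,28,-15,28,-13,1,-0.40
P12,37,27,29,30,19,39,5
P13,45,29,36,30,33,79,5
P14,11,4,61,4,66,27,4
P15,30,9,69,15,50,100,7
P16,31,15,53,24,25,80,10
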