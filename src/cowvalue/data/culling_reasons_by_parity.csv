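reason,p1,p2,p3,p4,p5,p6,p7,p8,p9,p10,p11,p12
calving_issues,2,2,2,5,2,1,1,0,0,0,1,1
others,11,8,5,3,2,1,4,0,2,2,0,1
respiratory,1,2,0,0,0,0,0,0,0,0,0,0
udder_health,15,9,15,21,17,24,8,7,1,3,3,2
fertility,22,17,21,22,17,22,12,11,1,0,0,1
claw,6,3,6,8,3,5,3,2,3,1,1,0
slow_milking,1,0,2,0,0,0,0,0,0,0,0,0
sold_alive,39,13,13,3,4,2,2,0,0,0,0,0
metabolic,2,2,2,2,1,1,0,1,0,0,0,0
accident,5,8,6,5,3,4,1,0,1,0,1,0
inadequate_performance,19,11,9,5,4,3,1,2,0,0,0,0
somatic_cell_count,0,2,2,0,0,0,0,0,0,0,0,0
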