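cultivar,life_stage,duration_days,n_boxes,pupae_count,treated_estimate
Hayward,egg,0,12,2892,3082
Hayward,egg,5,12,973,2898
Hayward,egg,6,12,575,2898
Hayward,egg,7,12,232,2898
Hayward,egg,8,12,121,2898
Hayward,egg,10,12,2,2898
Hayward,L1,0,12,2420,2560
Hayward,L1,5,12,81,2427
Hayward,L1,6,12,16,2427
Hayward,L1,7,12,3,2427
Hayward,L1,8,12,1,2427
Hayward,L1,10,12,0,2427
Hayward,L2,0,12,2371,2473
Hayward,L2,5,12,399,2376
Hayward,L2,6,12,292,2376
Hayward,L2,7,12,78,2360
Hayward,L2,8,12,12,2376
Hayward,L2,10,12,2,2376
Hayward,L3,0,32,10039,10964
Hayward,L3,5,12,1176,2469
Hayward,L3,6,12,483,2469
Hayward,L3,7,12,242,2404
Hayward,L3,8,32,382,10044
Hayward,L3,10,31,55,9491
Hayward,L3,11,20,16,7575
Hayward,L3,13,19,1,7244
Hayward,L3,14,20,3,7575
Hayward,L3,16,20,0,7575
Hayward,L3,18,20,0,7575
Zesy002,egg,0,12,1597,1766
Zesy002,egg,5,12,466,1602
Zesy002,egg,6,12,335,1602
Zesy002,egg,7,12,142,1602
Zesy002,egg,8,12,41,1602
Zesy002,egg,10,12,0,1602
Zesy002,L1,0,12,1220,1294
Zesy002,L1,5,12,161,1224
Zesy002,L1,6,12,61,1224
Zesy002,L1,7,12,38,1224
Zesy002,L1,8,12,17,1224
Zesy002,L1,10,12,0,1224
Zesy002,L2,0,12,1402,1593
Zesy002,L2,5,12,255,1407
Zesy002,L2,6,12,108,1407
Zesy002,L2,7,12,65,1407
Zesy002,L2,8,12,14,1407
Zesy002,L2,10,12,0,1407
Zesy002,L3,0,32,3875,4404
Zesy002,L3,5,12,467,1710
Zesy002,L3,6,12,310,1710
Zesy002,L3,7,12,177,1710
Zesy002,L3,8,31,97,3817
Zesy002,L3,10,32,16,3875
Zesy002,L3,11,20,0,2165
Zesy002,L3,13,20,0,2165
Zesy002,L3,14,20,1,2165
Zesy002,L3,16,20,0,2165
Zesy002,L3,18,20,0,2165
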