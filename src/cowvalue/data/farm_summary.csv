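farm_id,breed,replaced_loss,not_replaced_loss,n_cows,replacement_rate
1,BV,-380.77,0,138,25.4
2,BV,0,-217,72,31.9
3,OB,0,-746,72,25.0
4,BV,10,0,40,20.0
5,BV,0,-11,74,17.6
6,BV,0,-100,89,28.1
7,BV,0,-209,45,33.3
8,BV,0,-13,55,3.6
9,OB,0,-84,37,24.3
10,BV,-25,-28,48,22.9
11,BV,-127,0,108,27.8
12,BV,0,-165,120,20.8
13,HO,-75,0,237,27.4
14,HO,0,-220,134,25.4
15,BV,0,-29,44,20.5
16,HO,-7,-178,167,22.8
17,HO,-28,-273,164,26.2
18,MO,0,-31,77,11.7
19,MO,0,-258,139,20.1
20,HO,0,0,68,26.5
21,HO,-18,-44,139,17.3
22,HO,-115,-40,129,34.1
23,MO,0,-502,126,22.2
24,HO,-121,0,236,38.6
25,SF,-169,0,63,20.6
26,SF,-24,0,94,26.6
27,HO,0,-30,120,23.3
28,BV,0,-221,52,32.7
29,BV,0,-159,116,24.1
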