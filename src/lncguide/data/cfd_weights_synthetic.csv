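position,rna,dna,weight
1,A,A,0.54
1,A,C,0.36
1,A,G,0.54
1,C,A,0.36
1,C,C,0.54
1,C,T,0.54
1,G,A,0.54
1,G,G,0.54
1,G,T,0.36
1,U,C,0.54
1,U,G,0.81
1,U,T,0.54
2,A,A,0.5147
2,A,C,0.3432
2,A,G,0.5147
2,C,A,0.3432
2,C,C,0.5147
2,C,T,0.5147
2,G,A,0.5147
2,G,G,0.5147
2,G,T,0.3432
2,U,C,0.5147
2,U,G,0.7721
2,U,T,0.5147
3,A,A,0.4895
3,A,C,0.3263
3,A,G,0.4895
3,C,A,0.3263
3,C,C,0.4895
3,C,T,0.4895
3,G,A,0.4895
3,G,G,0.4895
3,G,T,0.3263
3,U,C,0.4895
3,U,G,0.7342
3,U,T,0.4895
4,A,A,0.4642
4,A,C,0.3095
4,A,G,0.4642
4,C,A,0.3095
4,C,C,0.4642
4,C,T,0.4642
4,G,A,0.4642
4,G,G,0.4642
4,G,T,0.3095
4,U,C,0.4642
4,U,G,0.6963
4,U,T,0.4642
5,A,A,0.4389
5,A,C,0.2926
5,A,G,0.4389
5,C,A,0.2926
5,C,C,0.4389
5,C,T,0.4389
5,G,A,0.4389
5,G,G,0.4389
5,G,T,0.2926
5,U,C,0.4389
5,U,G,0.6584
5,U,T,0.4389
6,A,A,0.4137
6,A,C,0.2758
6,A,G,0.4137
6,C,A,0.2758
6,C,C,0.4137
6,C,T,0.4137
6,G,A,0.4137
6,G,G,0.4137
6,G,T,0.2758
6,U,C,0.4137
6,U,G,0.6205
6,U,T,0.4137
7,A,A,0.3884
7,A,C,0.2589
7,A,G,0.3884
7,C,A,0.2589
7,C,C,0.3884
7,C,T,0.3884
7,G,A,0.3884
7,G,G,0.3884
7,G,T,0.2589
7,U,C,0.3884
7,U,G,0.5826
7,U,T,0.3884
8,A,A,0.3632
8,A,C,0.2421
8,A,G,0.3632
8,C,A,0.2421
8,C,C,0.3632
8,C,T,0.3632
8,G,A,0.3632
8,G,G,0.3632
8,G,T,0.2421
8,U,C,0.3632
8,U,G,0.5447
8,U,T,0.3632
9,A,A,0.3379
9,A,C,0.2253
9,A,G,0.3379
9,C,A,0.2253
9,C,C,0.3379
9,C,T,0.3379
9,G,A,0.3379
9,G,G,0.3379
9,G,T,0.2253
9,U,C,0.3379
9,U,G,0.5068
9,U,T,0.3379
10,A,A,0.3126
10,A,C,0.2084
10,A,G,0.3126
10,C,A,0.2084
10,C,C,0.3126
10,C,T,0.3126
10,G,A,0.3126
10,G,G,0.3126
10,G,T,0.2084
10,U,C,0.3126
10,U,G,0.4689
10,U,T,0.3126
11,A,A,0.2874
11,A,C,0.1916
11,A,G,0.2874
11,C,A,0.1916
11,C,C,0.2874
11,C,T,0.2874
11,G,A,0.2874
11,G,G,0.2874
11,G,T,0.1916
11,U,C,0.2874
11,U,G,0.4311
11,U,T,0.2874
12,A,A,0.2621
12,A,C,0.1747
12,A,G,0.2621
12,C,A,0.1747
12,C,C,0.2621
12,C,T,0.2621
12,G,A,0.2621
12,G,G,0.2621
12,G,T,0.1747
12,U,C,0.2621
12,U,G,0.3932
12,U,T,0.2621
13,A,A,0.2368
13,A,C,0.1579
13,A,G,0.2368
13,C,A,0.1579
13,C,C,0.2368
13,C,T,0.2368
13,G,A,0.2368
13,G,G,0.2368
13,G,T,0.1579
13,U,C,0.2368
13,U,G,0.3553
13,U,T,0.2368
14,A,A,0.2116
14,A,C,0.1411
14,A,G,0.2116
14,C,A,0.1411
14,C,C,0.2116
14,C,T,0.2116
14,G,A,0.2116
14,G,G,0.2116
14,G,T,0.1411
14,U,C,0.2116
14,U,G,0.3174
14,U,T,0.2116
15,A,A,0.1863
15,A,C,0.1242
15,A,G,0.1863
15,C,A,0.1242
15,C,C,0.1863
15,C,T,0.1863
15,G,A,0.1863
15,G,G,0.1863
15,G,T,0.1242
15,U,C,0.1863
15,U,G,0.2795
15,U,T,0.1863
16,A,A,0.1611
16,A,C,0.1074
16,A,G,0.1611
16,C,A,0.1074
16,C,C,0.1611
16,C,T,0.1611
16,G,A,0.1611
16,G,G,0.1611
16,G,T,0.1074
16,U,C,0.1611
16,U,G,0.2416
16,U,T,0.1611
17,A,A,0.1358
17,A,C,0.0905
17,A,G,0.1358
17,C,A,0.0905
17,C,C,0.1358
17,C,T,0.1358
17,G,A,0.1358
17,G,G,0.1358
17,G,T,0.0905
17,U,C,0.1358
17,U,G,0.2037
17,U,T,0.1358
18,A,A,0.1105
18,A,C,0.0737
18,A,G,0.1105
18,C,A,0.0737
18,C,C,0.1105
18,C,T,0.1105
18,G,A,0.1105
18,G,G,0.1105
18,G,T,0.0737
18,U,C,0.1105
18,U,G,0.1658
18,U,T,0.1105
19,A,A,0.0853
19,A,C,0.0568
19,A,G,0.0853
19,C,A,0.0568
19,C,C,0.0853
19,C,T,0.0853
19,G,A,0.0853
19,G,G,0.0853
19,G,T,0.0568
19,U,C,0.0853
19,U,G,0.1279
19,U,T,0.0853
20,A,A,0.06
20,A,C,0.04
20,A,G,0.06
20,C,A,0.04
20,C,C,0.06
20,C,T,0.06
20,G,A,0.06
20,G,G,0.06
20,G,T,0.04
20,U,C,0.06
20,U,G,0.09
20,U,T,0.06
PAM,NGG,-,1.0
PAM,NAG,-,0.26
PAM,other,-,0.0
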