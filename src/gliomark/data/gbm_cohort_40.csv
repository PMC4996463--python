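patient_id,arm,os_days,event,v_i_cm3,g_h,mgmt
1,BVZ-,70,1,14.182,0.611,methylated
2,BVZ-,71,1,0.070,0.444,
3,BVZ-,71,1,0.439,0.292,unmethylated
4,BVZ-,82,1,39.114,0.719,unmethylated
5,BVZ-,86,1,8.699,0.609,unmethylated
6,BVZ-,102,1,3.640,0.562,unmethylated
7,BVZ-,126,1,1.422,0.395,unmethylated
8,BVZ-,132,1,8.243,0.572,unmethylated
9,BVZ-,144,1,2.384,0.467,unmethylated
10,BVZ-,176,1,10.236,0.589,unmethylated
11,BVZ-,227,1,16.513,0.621,
12,BVZ-,245,1,2.349,0.646,
13,BVZ-,320,1,14.882,0.505,
14,BVZ-,375,1,30.470,0.623,unmethylated
15,BVZ-,416,1,3.695,0.453,methylated
16,BVZ-,422,1,0.872,0.539,methylated
17,BVZ-,453,1,0.054,0.235,unmethylated
18,BVZ-,494,1,26.232,0.589,methylated
19,BVZ-,533,1,1.527,0.412,methylated
20,BVZ-,584,1,20.928,0.581,
21,BVZ-,629,1,0.825,0.610,
22,BVZ-,909,1,0.353,0.725,
23,BVZ-,1205,1,1.546,0.402,unmethylated
24,BVZ+,72,1,2.979,0.752,methylated
25,BVZ+,121,1,4.135,0.623,unmethylated
26,BVZ+,128,1,3.866,0.635,methylated
27,BVZ+,131,1,12.598,0.607,unmethylated
28,BVZ+,213,1,6.401,0.792,methylated
29,BVZ+,294,1,6.875,0.633,methylated
30,BVZ+,311,1,30.054,0.721,
31,BVZ+,336,1,19.244,0.698,unmethylated
32,BVZ+,395,1,0.220,0.588,unmethylated
33,BVZ+,416,1,4.486,0.544,methylated
34,BVZ+,511,1,11.819,0.662,
35,BVZ+,683,1,0.011,0.368,
36,BVZ+,803,1,11.677,0.531,methylated
37,BVZ+,894,1,1.884,0.601,methylated
38,BVZ+,932,1,7.473,0.723,
39,BVZ+,1363,1,0.093,0.346,methylated
40,BVZ+,1592,1,0.682,0.509,methylated
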