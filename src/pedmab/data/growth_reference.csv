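age_years,weight_male_kg,weight_female_kg,brain_frac
2,12.5,12.0,0.80
3,14.3,13.9,0.86
4,16.3,15.9,0.90
5,18.4,17.9,0.93
6,20.7,20.2,0.95
7,23.1,22.8,0.96
8,25.8,25.5,0.97
9,28.7,29.0,0.975
10,32.0,32.5,0.98
11,36.0,37.0,0.985
12,40.5,41.5,0.99
13,45.8,45.8,1.00
14,51.0,49.4,1.00
15,56.3,51.7,1.00
16,60.8,53.5,1.00
17,64.4,54.9,1.00
18,67.0,56.6,1.00
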