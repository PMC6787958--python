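month,temp_mean,temp_min,temp_max,temp_sd,rain24_mean,rain24_min,rain24_max,rain24_sd,wind_mean,wind_min,wind_max,wind_sd
1,12.3,1.9,27.0,3.1,0.60,0.00,11.22,1.70,8.2,0.0,49.0,5.9
2,17.7,1.1,31.0,4.5,0.05,0.00,3.89,0.28,9.9,0.0,36.7,6.0
3,20.0,6.7,33.9,4.0,0.04,0.00,2.02,0.14,10.5,0.0,55.7,7.0
4,22.5,10.6,36.0,3.7,0.30,0.00,4.56,0.75,11.0,0.0,50.8,7.5
5,25.1,13.1,38.5,3.8,0.05,0.00,1.21,0.17,10.1,0.0,38.7,5.9
6,33.2,19.9,48.8,4.1,0.01,0.00,1.09,0.05,10.5,0.1,35.3,5.3
7,34.9,22.4,45.7,3.5,0.10,0.00,2.91,0.33,11.6,0.0,47.3,5.3
8,33.9,22.0,45.5,3.3,0.07,0.00,1.74,0.17,9.2,0.0,39.7,5.1
9,28.9,16.0,42.3,3.7,0.19,0.00,6.34,0.79,9.1,0.0,35.4,5.7
10,25.0,14.8,36.3,3.5,0.07,0.00,2.83,0.37,8.1,0.0,34.4,4.8
11,18.3,3.6,33.5,4.2,0.09,0.00,3.21,0.31,8.4,0.0,34.8,5.3
12,12.8,1.3,25.6,3.1,1.22,0.00,22.32,3.44,9.5,0.0,44.8,6.9
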