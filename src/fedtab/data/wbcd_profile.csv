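feature,mean,std,min,max
radius_mean,14.46,3.1,6.98,23.27
texture_mean,19.07,3.74,9.71,29.81
perimeter_mean,93.9,21.12,43.79,152.1
area_mean,675.59,294.56,143.5,1686.0
smoothness_mean,0.1,0.01,0.06,0.13
compactness_mean,0.1,0.04,0.02,0.23
concavity_mean,0.08,0.06,0.0,0.28
concave_points_mean,0.05,0.03,0.0,0.16
symmetry_mean,0.18,0.02,0.12,0.25
fractal_dimension_mean,0.06,0.01,0.05,0.08
radius_se,0.37,0.18,0.11,0.97
texture_se,1.09,0.38,0.36,2.24
perimeter_se,2.59,1.24,0.76,6.79
area_se,36.37,25.4,6.8,116.29
smoothness_se,0.01,0.0,0.0,0.01
compactness_se,0.02,0.01,0.0,0.06
concavity_se,0.03,0.01,0.0,0.08
concave_points_se,0.01,0.0,0.0,0.02
symmetry_se,0.02,0.01,0.01,0.03
fractal_dimension_se,0.0,0.0,0.0,0.01
radius_worst,16.72,4.27,7.93,28.01
texture_worst,25.66,5.47,12.02,42.65
perimeter_worst,109.71,28.99,50.41,187.33
area_worst,911.11,472.97,185.2,2405.48
smoothness_worst,0.13,0.02,0.08,0.19
compactness_worst,0.25,0.12,0.03,0.66
concavity_worst,0.27,0.17,0.0,0.77
concave_points_worst,0.12,0.06,0.0,0.26
symmetry_worst,0.29,0.05,0.18,0.43
fractal_dimension_worst,0.08,0.01,0.06,0.12
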