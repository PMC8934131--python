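sex,age_band,category,proportion,proportion_se,mean_minutes,mean_se
male,18-24,low,0.2747,0.0221,171.27,6.76
male,18-24,moderate,0.3820,0.0239,343.49,5.12
male,18-24,high,0.3433,0.0251,685.28,22.31
male,25-34,low,0.2433,0.0184,180.95,4.48
male,25-34,moderate,0.3171,0.0193,342.76,3.93
male,25-34,high,0.4396,0.0189,646.71,9.63
male,35-44,low,0.2481,0.0152,180.06,3.41
male,35-44,moderate,0.3090,0.0206,351.88,3.57
male,35-44,high,0.4430,0.0187,634.14,8.33
male,45-54,low,0.1871,0.0146,180.10,4.21
male,45-54,moderate,0.3506,0.0191,354.70,4.23
male,45-54,high,0.4623,0.0207,630.06,7.79
male,55-64,low,0.2572,0.0158,194.87,4.21
male,55-64,moderate,0.3715,0.0193,350.70,3.74
male,55-64,high,0.3713,0.0214,653.30,12.54
male,65-74,low,0.2979,0.0169,194.87,3.44
male,65-74,moderate,0.4231,0.0198,354.59,3.40
male,65-74,high,0.2789,0.0190,634.68,16.07
male,75+,low,0.2602,0.0254,186.70,6.91
male,75+,moderate,0.4258,0.0271,352.92,3.58
male,75+,high,0.3140,0.0281,623.90,20.38
female,18-24,low,0.3074,0.0251,175.27,4.50
female,18-24,moderate,0.3501,0.0264,362.73,4.42
female,18-24,high,0.3425,0.0269,617.30,12.28
female,25-34,low,0.3492,0.0158,164.47,3.24
female,25-34,moderate,0.3034,0.0158,349.08,3.61
female,25-34,high,0.3473,0.0179,621.41,8.65
female,35-44,low,0.4846,0.0141,160.16,3.06
female,35-44,moderate,0.2506,0.0158,348.97,3.54
female,35-44,high,0.2648,0.0127,620.21,7.76
female,45-54,low,0.3850,0.0207,163.02,3.89
female,45-54,moderate,0.3081,0.0176,343.66,2.89
female,45-54,high,0.3069,0.0176,618.50,7.76
female,55-64,low,0.3457,0.0157,182.06,3.54
female,55-64,moderate,0.3916,0.0169,340.54,3.02
female,55-64,high,0.2627,0.0148,639.73,9.81
female,65-74,low,0.3330,0.0181,173.92,4.76
female,65-74,moderate,0.4417,0.0196,346.12,2.59
female,65-74,high,0.2253,0.0164,627.60,16.60
female,75+,low,0.2622,0.0212,193.21,4.12
female,75+,moderate,0.4380,0.0260,356.87,3.99
female,75+,high,0.2998,0.0220,613.31,9.88
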