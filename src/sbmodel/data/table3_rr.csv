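disease,category,rr,ci_low,ci_high
breast_cancer,moderate,1.05,0.94,1.18
breast_cancer,high,1.22,1.08,1.39
colorectal_cancer,moderate,1.03,0.94,1.13
colorectal_cancer,high,1.16,1.07,1.26
endometrial_cancer,moderate,1.29,0.99,1.67
endometrial_cancer,high,1.54,1.29,1.83
type2_diabetes,moderate,1.13,0.94,1.35
type2_diabetes,high,1.31,1.15,1.48
stroke,moderate,1.05,0.95,1.15
stroke,high,1.21,1.07,1.37
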