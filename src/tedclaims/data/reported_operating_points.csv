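model,label,sensitivity_pct,specificity_pct,ppv_pct,npv_pct,plr,nlr,f1
rule,alg1,48.7,59.9,75.8,31.2,1.21,0.86,0.59
rule,alg2,23.6,90.4,86.4,31.5,2.47,0.84,0.37
rule,alg3,25.7,88.5,85.2,31.6,2.24,0.84,0.39
rule,alg4,27.0,87.2,84.5,31.7,2.11,0.84,0.41
rule,alg5,17.8,93.5,87.6,30.6,2.74,0.88,0.30
rule,alg6,33.4,86.8,86.7,33.6,2.54,0.77,0.48
full,0.60,86.8,29.4,76.0,46.3,1.23,0.45,0.81
full,0.65,70.8,55.4,80.4,42.4,1.59,0.53,0.75
full,0.70,57.9,70.3,83.4,39.3,1.95,0.60,0.68
full,0.75,49.0,78.4,85.4,37.3,2.27,0.65,0.62
full,0.80,40.1,85.4,87.6,35.6,2.75,0.70,0.55
full,0.85,27.7,92.5,90.5,33.2,3.69,0.78,0.43
simplified,0.60,70.1,51.2,78.8,39.9,1.44,0.58,0.74
simplified,0.65,61.9,63.0,81.2,39.0,1.67,0.61,0.70
simplified,0.70,56.7,69.4,82.7,38.3,1.85,0.62,0.67
simplified,0.75,49.3,77.2,84.8,37.1,2.16,0.66,0.62
simplified,0.80,39.3,84.8,86.9,35.1,2.58,0.72,0.54
simplified,0.85,28.5,91.7,89.8,33.2,3.43,0.78,0.43
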