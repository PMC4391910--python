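# Proportional LDL cholesterol reductions by statin and daily dose, with 95% CIs,
# from the meta-analysis of Law, Wald & Rudnicka (BMJ 2003;326:1423): absolute LDL
# reductions standardised to a pre-treatment LDL of 4.8 mmol/L, expressed as proportions.
statin,strength_mg,ldl_reduction,ldl_ci_low,ldl_ci_high
atorvastatin,10,0.37,0.35,0.39
atorvastatin,20,0.43,0.41,0.45
atorvastatin,40,0.49,0.46,0.52
atorvastatin,80,0.55,0.51,0.59
fluvastatin,20,0.21,0.18,0.24
fluvastatin,40,0.27,0.24,0.30
fluvastatin,80,0.33,0.29,0.37
pravastatin,10,0.20,0.18,0.22
pravastatin,20,0.24,0.22,0.26
pravastatin,40,0.29,0.27,0.31
rosuvastatin,5,0.38,0.36,0.40
rosuvastatin,10,0.43,0.41,0.45
rosuvastatin,20,0.48,0.45,0.51
rosuvastatin,40,0.53,0.49,0.57
simvastatin,5,0.23,0.20,0.26
simvastatin,10,0.27,0.25,0.29
simvastatin,20,0.32,0.30,0.34
simvastatin,40,0.37,0.35,0.39
simvastatin,80,0.42,0.39,0.45
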