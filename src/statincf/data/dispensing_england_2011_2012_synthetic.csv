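# SYNTHETIC reconstruction of statin units dispensed in England, 2011 + 2012 combined.
# Relative volumes approximate the Prescription Cost Analysis (England) publications for
# 2011 and 2012, scaled so the grand total matches the published consumption of roughly
# 4.07 billion units (one tablet = one unit; 5 ml of liquid = one unit). The exact
# per-strength quantities are a best-effort reconstruction, not the source data.
statin,strength_mg,form,units
simvastatin,5,solid,25000000
simvastatin,10,solid,220000000
simvastatin,20,solid,700000000
simvastatin,40,solid,1380000000
simvastatin,80,solid,150000000
simvastatin,40,liquid,4000000
simvastatin+ezetimibe,20,combination_with_ezetimibe,10000000
simvastatin+ezetimibe,40,combination_with_ezetimibe,30000000
atorvastatin,10,solid,295000000
atorvastatin,20,solid,275000000
atorvastatin,30,solid,2000000
atorvastatin,40,solid,215000000
atorvastatin,80,solid,100000000
pravastatin,10,solid,68000000
pravastatin,20,solid,152000000
pravastatin,40,solid,180000000
rosuvastatin,5,solid,56000000
rosuvastatin,10,solid,94000000
rosuvastatin,20,solid,44000000
rosuvastatin,40,solid,14000000
fluvastatin,20,solid,16000000
fluvastatin,40,solid,23000000
fluvastatin,80,solid,26000000
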