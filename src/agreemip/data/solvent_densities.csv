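# Liquid densities at ~20-25 C in g/mL, rounded to three decimals, for
# converting reported solvent volumes to masses. Values are the standard
# handbook figures (CRC Handbook of Chemistry and Physics, 97th ed.).
name,density_g_per_ml
water,0.997
acetonitrile,0.786
methanol,0.792
ethanol,0.789
isopropanol,0.785
acetone,0.784
toluene,0.867
xylene,0.861
chloroform,1.489
dichloromethane,1.325
ethyl acetate,0.902
diethyl ether,0.713
tetrahydrofuran,0.889
hexane,0.655
cyclohexane,0.779
acetic acid,1.049
formic acid,1.220
pyridine,0.982
dimethyl sulfoxide,1.100
dimethylformamide,0.944
dimethylacetamide,0.937
ethylene glycol,1.113
glycerol,1.261
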