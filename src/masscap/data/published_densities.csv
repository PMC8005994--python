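agent,bulk_density_g_ml,bulk_density_sd,compressed_density_g_ml,compressed_density_sd,density_increase_pct,density_increase_sd,bulking_mass_g,bulking_mass_sd
m35,0.531,0.003,0.705,0.011,24.7,1.78,8.618,0.072
la,0.564,0.006,0.781,0.027,27.7,3.15,9.274,0.170
mcc,0.392,0.003,0.443,0.002,11.3,1.64,6.071,0.038
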