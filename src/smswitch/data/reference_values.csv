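# Transcribed reference values: published single-molecule CoSMoS measurements of the
# E. coli clamp loader / beta clamp / polymerase system. These are the study conditions
# the synthetic scenarios install as generator parameters and the recovery targets the
# pipeline is checked against. Empty sem = not reported.
key,value,sem,units,description
loader_dna_lifetime,1.20,0.05,s,gamma clamp loader complex on bare DNA; single-channel acquisition
loader_clamp_dna_lifetime,0.41,0.01,s,gamma clamp loader during clamp loading (with clamp and ATP); single-channel acquisition
atpgs_complex_lifetime,2.7,0.2,s,loader-clamp complex arriving and releasing together with ATPgammaS
clamp_lifetime,1429.7,177.0,s,loaded beta clamp on DNA after loader washout; 10 s interval acquisition
unload_release_lag,4.1,0.4,s,lag from loader arrival at a pre-loaded clamp to clamp release (productive unloading)
unload_loader_lifetime,10.8,1.2,s,total loader dwell during productive clamp unloading
unload_nonproductive_lifetime,2.5,0.1,s,loader dwell for encounters that do not unload the clamp
unload_nonproductive_fraction,53,,%,fraction of loader encounters with a pre-loaded clamp that do not unload it
pol1_dna_lifetime,42.2,1.8,s,Pol I Klenow fragment on bare DNA
pol3_clamp_lifetime,15.7,1.1,s,Pol IIIcore on clamp-DNA; matched substrate; no dNTPs
pol3_clamp_lifetime_dntp,16.1,1.0,s,Pol IIIcore on clamp-DNA with dATP/dTTP (idling)
pol3_lifetime_lesion,17.6,2.1,s,Pol IIIcore on clamp-DNA bearing an N2-furfuryl-dG lesion; no dNTPs
pol3_lifetime_mismatch,19.0,1.4,s,Pol IIIcore on clamp-DNA bearing a G-T mismatch; no dNTPs
pol3_eps_weak_lifetime,7.9,1.2,s,Pol IIIcore with weakened epsilon clamp-groove motif (QTSAAA)
pol3_eps_strong_lifetime,40.2,8.7,s,Pol IIIcore with enhanced epsilon clamp-groove motif (QTSLPL)
tau_complex_lifetime,14.8,0.9,s,tau clamp loader complex + Pol IIIcore joint dwell on clamp-DNA
pol4_lifetime,14.2,1.8,s,Pol IV wild type on clamp-DNA
pol4_groove_lifetime,2.7,0.2,s,Pol IV clamp-groove mutant (QLVAGA) on clamp-DNA
pol4_rim_lifetime,14.9,1.7,s,Pol IV clamp-rim mutant (AGA) on clamp-DNA
pol2_lifetime,10.4,1.3,s,Pol II wild type on clamp-DNA
pol2_groove_lifetime,4.4,0.8,s,Pol II clamp-groove mutant (QLGAA) on clamp-DNA
coloc_pol3_pol4_lifetime,8.2,0.6,s,co-localization time of Pol IIIcore and Pol IV on one clamp-DNA
switch_lag_30_6,32.5,4.6,s,Pol IIIcore release to Pol IV arrival lag; 30 nM Pol IIIcore / 6 nM Pol IV
switch_lag_30_30,20.3,3.5,s,Pol IIIcore release to Pol IV arrival lag; 30 nM / 30 nM
switch_lag_30_150,5.9,0.5,s,Pol IIIcore release to Pol IV arrival lag; 30 nM / 150 nM
switch_lag_150_150,3.5,0.2,s,Pol IIIcore release to Pol IV arrival lag; 150 nM / 150 nM
switch_lag_tau_30,11.3,1.3,s,Pol IIIcore release to Pol IV arrival lag; tau-complex / 30 nM Pol IV
exchange_pct_3to4_30_30,70,,%,Pol IIIcore -> Pol IV switches among classified pairs; 30 nM / 30 nM
exchange_pct_4to3_30_30,22,,%,Pol IV -> Pol IIIcore switches among classified pairs; 30 nM / 30 nM
exchange_pct_coloc_30_30,9,,%,Pol IIIcore + Pol IV co-localizations among classified pairs; 30 nM / 30 nM
bleach_atto488_lifetime,274.4,16.5,s,apparent Atto 488 lifetime on DNA-bound clamps under standard acquisition
bleach_atto565_lifetime,145.7,7.5,s,apparent Atto 565 lifetime on DNA-bound clamps under standard acquisition
bleach_atto647n_lifetime,93.0,7.4,s,apparent Atto 647N lifetime on DNA-bound clamps under standard acquisition
label_eff_pol3a_coloc,67,,%,Pol IIIalpha labeling efficiency from alpha/epsilon co-binding events
label_eff_eps_coloc,71,,%,epsilon labeling efficiency from alpha/epsilon co-binding events
label_eff_gamma_abs,85,,%,gamma/tau loader complex labeling efficiency by absorbance
label_eff_clamp_abs,68,,%,beta clamp monomer labeling efficiency by absorbance
label_eff_pol1_abs,100,,%,Pol I Klenow labeling efficiency by absorbance
label_eff_pol3a_abs,60,,%,Pol IIIalpha labeling efficiency by absorbance
label_eff_eps_abs,78,,%,epsilon labeling efficiency by absorbance
label_eff_pol4_abs,62,,%,Pol IV labeling efficiency by absorbance
label_eff_pol2_abs,66,,%,Pol II labeling efficiency by absorbance
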