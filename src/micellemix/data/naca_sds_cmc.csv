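# Temperature-dependent critical micelle concentrations for the equimolar
# NaCA-SDS system (fluorimetric determinations): pure NaCA (cmc1), pure SDS
# (cmc2) and the 1:1 mixture (cmc_mix), all in mM.
temperature_C,cmc1_mM,cmc2_mM,cmc_mix_mM,alpha1
0,9.00,10.00,4.09,0.5
5,9.50,10.23,4.01,0.5
10,10.00,10.47,4.01,0.5
15,10.50,10.82,4.17,0.5
20,11.00,11.31,4.12,0.5
25,11.50,11.98,4.07,0.5
30,12.00,12.40,4.21,0.5
35,12.50,13.11,4.40,0.5
40,13.00,13.58,4.54,0.5
45,13.50,14.03,4.76,0.5
50,14.00,14.78,6.78,0.5
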