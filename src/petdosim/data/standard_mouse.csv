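organ,mass_g,density_g_per_ml
brain,0.45,1.04
liver,1.75,1.05
kidneys,0.50,1.05
heart,0.16,1.05
spleen,0.10,1.06
lung,0.20,0.60
testes,0.20,1.04
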