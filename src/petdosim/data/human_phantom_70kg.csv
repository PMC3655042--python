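organ,mass_g
brain,1420.0
liver,1910.0
kidneys,299.0
heart,316.0
spleen,183.0
lung,1000.0
testes,39.1
bladder,47.6
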