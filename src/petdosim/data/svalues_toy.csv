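target,brain,heart,kidneys,liver,lung,spleen,testes,bladder,remainder
adrenals,1.0000E-04,1.0000E-04,2.0000E-03,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
brain,2.0000E-02,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
breasts,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
gallbladder wall,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
lli wall,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,4.5000E-03
small intestine,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,4.5000E-03
stomach wall,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,4.5000E-03
uli wall,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
heart wall,1.0000E-04,7.0000E-02,1.0000E-04,2.0000E-03,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
kidneys,1.0000E-04,1.0000E-04,7.5000E-02,2.0000E-03,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,4.5000E-03
liver,1.0000E-04,2.0000E-03,2.0000E-03,1.6000E-02,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
lungs,1.0000E-04,2.0000E-03,1.0000E-04,2.0000E-03,2.8000E-02,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
muscle,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
ovaries,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,4.5000E-03
pancreas,1.0000E-04,1.0000E-04,2.0000E-03,2.0000E-03,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,4.5000E-03
red marrow,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
osteogenic cells,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
skin,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
spleen,1.0000E-04,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,1.2000E-01,1.0000E-04,1.0000E-04,4.5000E-03
testes,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,5.5000E-01,2.0000E-03,4.5000E-03
thymus,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
thyroid,2.0000E-03,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,4.5000E-03
urinary bladder wall,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,5.0000E-01,4.5000E-03
uterus,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,1.0000E-04,2.0000E-03,4.5000E-03
total body,6.0000E-04,1.5000E-04,1.5000E-04,8.0000E-04,4.0000E-04,1.0000E-04,2.0000E-05,2.0000E-04,4.5000E-03
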