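tissue,volume_mL,vasc_frac,endo_frac,int_frac,plasma_flow_mL_day,lymph_frac,fcrn_uM
lung,1000,0.105,0.005,0.19,144000,0.002,49.8
heart,341,0.06,0.005,0.14,187200,0.002,49.8
kidney,332,0.06,0.005,0.15,864000,0.002,49.8
brain,1450,0.04,0.005,0.18,547200,0.002,49.8
muscle,30078,0.03,0.005,0.13,604800,0.002,49.8
skin,3408,0.04,0.005,0.30,230400,0.002,49.8
adipose,13465,0.02,0.005,0.135,201600,0.002,49.8
bone,10165,0.03,0.005,0.10,201600,0.002,49.8
liver,2143,0.11,0.005,0.20,273600,0.002,49.8
spleen,221,0.22,0.005,0.15,108000,0.002,49.8
gut,1100,0.07,0.005,0.19,547200,0.002,49.8
pancreas,104,0.06,0.005,0.17,36000,0.002,49.8
thymus,6.4,0.05,0.005,0.15,2880,0.002,49.8
other,4852,0.04,0.005,0.18,144000,0.002,49.8
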