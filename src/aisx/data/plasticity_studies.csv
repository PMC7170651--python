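study,group,L_initial_um,x_half_initial_um,L_final_um,x_half_final_um,observed_shift_mV
chick nucleus magnocellularis,plasticity,9.6,13.3,19.5,18.4,-4
hippocampal cultures (excitatory),plasticity,34.8,20.9,33.6,27.2,4.3
hippocampal dentate granule cells in culture,plasticity,19.2,10.4,15.7,7.85,-1.1
olfactory bulb dopaminergic neurons in culture,plasticity,11.7,21.1,14.2,15.5,-0.4
chick nucleus laminaris (low),development,30.3,24.8,23.9,19.9,-12.7
chick nucleus laminaris (middle),development,28.8,24.8,14.4,28.3,
chick nucleus laminaris (high),development,26.5,26.6,9.8,50.1,-14.3
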