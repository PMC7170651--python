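cell_type,soma_diameter_um,soma_sd_um,ais_diameter_um,ais_sd_um
adult cat olivary cells,21.7,3.7,1.1,0.3
adult rat CA3 pyramidal cells,20.9,3.2,1.2,0.4
adult rat Purkinje cells,21.9,1.9,0.7,0.2
adult mouse cerebellar granule cells,5.9,0.3,0.2,
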