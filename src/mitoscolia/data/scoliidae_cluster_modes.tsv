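taxon	cluster1	cluster2
Austroscolia_ruficeps	mode1	mode3
Carinoscolia_vittifrons	mode1	mode3
Megascolia_azurea	mode1	mode3
Scolia_sikkimensis	mode1	mode3
Scolia_superciliaris	mode1	mode3
Scolia_sp	mode1	mode3
Liacos_erythrosoma	?	mode3
Colpa_tartara	mode1	mode3
Megacampsomeris_binghami	mode2	mode4
Megacampsomeris_farrenwhitei	mode2	mode4
Megacampsomeris_prismatica	mode2	mode4
Micromeriella_marginella	mode2	mode4
Sericocampsomeris_flavomaculata	mode2	mode4
Campsomeriella_annulata	?	?
Phalerimeris_phalerata	mode2	mode4
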