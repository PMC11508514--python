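((Campsomeriella_annulata,(Phalerimeris_phalerata,(Micromeriella_marginella,(Sericocampsomeris_flavomaculata,(Megacampsomeris_prismatica,(Megacampsomeris_binghami,Megacampsomeris_farrenwhitei)))))),(Colpa_tartara,((Austroscolia_ruficeps,(Scolia_sp,(Scolia_sikkimensis,Scolia_superciliaris))),(Megascolia_azurea,(Liacos_erythrosoma,Carinoscolia_vittifrons)))));
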