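((solemys_sp:32,solemys_vermiculata:32):80,((dorkota_vasconica:23,(podocnemis_erythrocephala:90,(bothremys_barberi:5,taphrosphys_sulcatus:12):10):60):25,((carettochelys_insculpta:140,(pelodiscus_sinensis:115,trionychidae_indet:5):25):25,((plesiochelys_sp:3,(caretta_caretta:110,(archelon_ischyros:20,ctenochelys_stenoporus:15):20):48):2,(terrapene_carolina_tringuis:60,(geochelone_elegans:50,(hesperotestudo_sp:4.5,hesperotestudo_crassiscuta:4.5):45):10):100):5):10):5);
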