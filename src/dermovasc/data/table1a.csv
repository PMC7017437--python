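specimen_id,taxon,clade,porosity,lifestyle,region,ornamented,age,collection_number
hesperotestudo_sp_1,Hesperotestudo sp.,Testudinata,0.07,terrestrial,flat osteoderm,no,Pleistocene,TMM 30967-1010.1
hesperotestudo_sp_2,Hesperotestudo sp.,Testudinata,0.21,terrestrial,spiked osteoderm,no,Pleistocene,TMM 30967-1010.2
terrapene_carolina_tringuis_1,Terrapene carolina tringuis,Testudinata,0.40,terrestrial,neural,no,extant,FMNH 211806
terrapene_carolina_tringuis_2,Terrapene carolina tringuis,Testudinata,0.22,terrestrial,costal (right),no,extant,FMNH 211806
dorkota_vasconica_1,Dorkota vasconica,Testudinata,0.21,freshwater,costal,no,Barremian,MCNA 14366
dorkota_vasconica_2,Dorkota vasconica,Testudinata,0.24,freshwater,neural,no,Barremian,MCNA 14372
podocnemis_erythrocephala_1,Podocnemis erythrocephala,Testudinata,0.15,freshwater,sample costal,no,extant,YPM 11853
solemys_sp_1,Solemys sp.,Testudinata,0.07,terrestrial,costal fragment,yes,Maastrichtyian,UPUAM-14001
solemys_vermiculata_1,Solemys vermiculata,Testudinata,0.14,terrestrial,costal fragment,yes,Maastrichtyian,MCNA 15047
solemys_vermiculata_2,Solemys vermiculata,Testudinata,0.16,terrestrial,shell fragment,yes,Maastrichtyian,MCNA 15046
carettochelys_insculpta_1,Carettochelys insculpta,Testudinata,0.10,freshwater,costal (right 7th),yes,extant,WU-SILS RH1044
pelodiscus_sinensis_1,Pelodiscus sinensis,Testudinata,0.11,freshwater,costal,yes,extant,NSMT-H 6600
trionychidae_indet_1,Trionychidae indet.,Testudinata,0.11,freshwater,costal,yes,Aptian-Albian,ZIN PH 102
trionychidae_indet_2,Trionychidae indet.,Testudinata,0.10,freshwater,costal,yes,early Cenomanian,ZIN PH 122
trionychidae_indet_3,Trionychidae indet.,Testudinata,0.09,freshwater,costal,yes,Barremian-Aptian,FPDM V0127
bothremys_barberi_1,Bothremys barberi,Testudinata,0.31,marine,costal,no,Campanian,FM P27406 (FMNH)
bothremys_barberi_2,Bothremys barberi,Testudinata,0.32,marine,costal,no,Campanian,FM P27406 (FMNH)
bothremys_barberi_3,Bothremys barberi,Testudinata,0.30,marine,neural,no,Campanian,FM P27406 (FMNH)
caretta_caretta_1,Caretta caretta,Testudinata,0.39,marine,costal,no,extant,FMNH 98963
caretta_caretta_2,Caretta caretta,Testudinata,0.33,marine,hyoplastron,no,extant,FMNH 98963
archelon_ischyros_1,Archelon ischyros,Testudinata,0.26,marine,shell fragment,no,Late Cretaceous,YPM 1783
plesiochelys_sp_1,Plesiochelys sp.,Testudinata,0.18,marine,neural,no,Kimmeridgian,NMS 8730
taphrosphys_sulcatus_1,Taphrosphys sulcatus,Testudinata,0.34,marine,costal,no,Maastrichtian,YPM 40288
taphrosphys_sulcatus_2,Taphrosphys sulcatus,Testudinata,0.35,marine,neural,no,Maastrichtian,YPM 40288
ctenochelys_stenoporus_1,Ctenochelys stenoporus,Testudinata,0.36,marine,neural,no,Campanian,FM PR 442
geochelone_elegans_1,Geochelone elegans,Testudinata,0.14,terrestrial,costal,no,extant,IPB 561-C
geochelone_elegans_2,Geochelone elegans,Testudinata,0.10,terrestrial,costal,no,extant,IPB 561-C
geochelone_elegans_3,Geochelone elegans,Testudinata,0.07,terrestrial,neural,no,extant,IPB 561-C
hesperotestudo_crassiscuta_1,Hesperotestudo crassiscuta,Testudinata,0.19,terrestrial,neural,no,Pleistocene,ROM 5540
hesperotestudo_crassiscuta_2,Hesperotestudo crassiscuta,Testudinata,0.30,terrestrial,plaston fragment,no,Pleistocene,ROM 5541
hesperotestudo_crassiscuta_3,Hesperotestudo crassiscuta,Testudinata,0.28,terrestrial,shell fragment,no,Pleistocene,ROM 5542
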