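specimen_id,taxon,clade,porosity,lifestyle,region,ornamented,age,collection_number
araripesuchus_tsangatsangana_1,Araripesuchus tsangatsangana,Pseudosuchia,0.05,terrestrial,n.a.,yes,Late Cretaceous,UA 9966
batrachotomus_kupferzellensis_1,Batrachotomus kupferzellensis,Pseudosuchia,0.01,terrestrial,paramedian pre-caudal,yes,Late Ladinian,SMNS 80317
prestosuchus_chiniquensis_1,Prestosuchus chiniquensis,Pseudosuchia,0.05,terrestrial,sacral paramedian,yes,Late Ladinian/Early Carnian,BSPG ASXXV7
prestosuchus_loricatus_1,'Prestosuchus' loricatus,Pseudosuchia,0.04,terrestrial,pre-caudal paramedian,yes,Late Ladinian/Early Carnian,BSPG ASXXV46d
rauisuchus_tiradentes_1,Rauisuchus tiradentes,Pseudosuchia,0.16,terrestrial,pre-caudal paramedian,yes,Late Carnian/Early Norian,BSPG ASXXV121b
revueltosaurus_sp_1,Revueltosaurus sp.,Pseudosuchia,0.04,terrestrial,paramedian,yes,Norian,PEFO 33787
tikisuchus_romeri_1,Tikisuchus romeri,Pseudosuchia,0.14,terrestrial,pre-caudal paramedian,yes,Carnian,ISI R 305/1
simosuchus_clarki_1,Simosuchus clarki,Pseudosuchia,0.10,terrestrial,n.a.,no,Late Cretaceous,UA 9965
simosuchus_clarki_2,Simosuchus clarki,Pseudosuchia,0.07,terrestrial,n.a.,no,Late Cretaceous,UA 9965
yarasuchus_deccanensis_1,Yarasuchus deccanensis,Avemetatarsalia-outgroup,0.10,terrestrial,pre-caudal paramedian,yes,Anisian,ISI R 334
alligator_mississippiensis_1,Alligator mississippiensis,Pseudosuchia,0.15,semi-aquatic,n.a.,yes,extant,SMNS 10481b
allognathosuchus_wartheni_1,Allognathosuchus wartheni,Pseudosuchia,0.13,semi-aquatic,n.a.,yes,Wasatchian,UCMP 113731
crocodylus_niloticus_1,Crocodylus niloticus,Pseudosuchia,0.13,semi-aquatic,dorsal,yes,extant,"MNHN-AC-1920.90, PC"
diplocynodon_sp_1,Diplocynodon sp.,Pseudosuchia,0.23,semi-aquatic,n.a.,yes,Eocene-Miocene,IPB R144/1
diplocynodon_remensis_1,Diplocynodon remensis,Pseudosuchia,0.24,semi-aquatic,nuchal,yes,Thanetian,MNHN. F. No number
machimosaurus_hugii_1,Machimosaurus hugii,Pseudosuchia,0.22,semi-aquatic,n.a.,yes,Late Jurassic,SMNS 81608
sarcosuchus_imperator_1,Sarcosuchus imperator,Pseudosuchia,0.24,semi-aquatic,n.a.,yes,Upper Cretaceous,MNHN.F. GDF 380
steneosaurus_sp_1,Steneosaurus sp.,Pseudosuchia,0.07,semi-aquatic,n.a.,yes,Late Jurassic,NMS 752
steneosaurus_jugleri_1,Steneosaurus jugleri,Pseudosuchia,0.12,semi-aquatic,n.a.,yes,Late Jurassic,NMS 7152
paleosuchus_trigonatus_1,Paleosuchus trigonatus,Pseudosuchia,0.29,semi-aquatic,n.a.,yes,extant,MCL 420003939
protocaiman_peligrensis_1,Protocaiman peligrensis,Pseudosuchia,0.13,semi-aquatic,n.a.,yes,Danian,UCMP 131693
teleosaurus_cadomensis_1,Teleosaurus cadomensis,Pseudosuchia,0.22,semi-aquatic,n.a.,yes,Bathonian,MNHN Histo 1960
goniopholis_sp_1,Goniopholis sp.,Pseudosuchia,0.20,semi-aquatic,n.a.,yes,Oxfordian-Berriasian,MNHN Histo 1727
borealosuchus_sp_1,Borealosuchus sp.,Pseudosuchia,0.17,semi-aquatic,n.a.,yes,Campanian-Ypresian,UCMP 133903
mahajangasuchus_insignis_1,Mahajangasuchus insignis,Pseudosuchia,0.17,semi-aquatic,n.a.,yes,Campanian,UA 9962
brachychampsa_montana_1,Brachychampsa montana,Pseudosuchia,0.22,semi-aquatic,n.a.,yes,Maastrichtian,UCMP 133901
osteolaemus_tetraspis_1,Osteolaemus tetraspis,Pseudosuchia,0.12,semi-aquatic,n.a.,yes,extant,MNHN-AC-1991.4488
paleosuchus_palpebrosus_1,Paleosuchus palpebrosus,Pseudosuchia,0.11,semi-aquatic,n.a.,yes,extant,MNHN.AC-1909.204
caiman_crocodilus_1,Caiman crocodilus,Pseudosuchia,0.27,semi-aquatic,nuchal,yes,extant,Sorbonne Universite - NA
borealosuchus_wilsoni_1,Borealosuchus wilsoni,Pseudosuchia,0.18,semi-aquatic,n.a.,yes,Ypresian,UCMP 131696
paratypothorax_sp_1,Paratypothorax sp.,Pseudosuchia,0.25,terrestrial,paramedian,yes,Late Triassic,PEFO 5030
aetosaurus_scagliai_1,Aetosaurus scagliai,Pseudosuchia,0.05,terrestrial,paramedian,yes,Late Triassic,PVL 2073
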