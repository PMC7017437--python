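(yarasuchus_deccanensis:5,((revueltosaurus_sp:20,(paratypothorax_sp:15,aetosaurus_scagliai:13):10):13,(batrachotomus_kupferzellensis:8,((prestosuchus_chiniquensis:3,prestosuchus_loricatus:3):4,(tikisuchus_romeri:10,(rauisuchus_tiradentes:12,((simosuchus_clarki:52,(araripesuchus_tsangatsangana:30,mahajangasuchus_insignis:28):20):115,((teleosaurus_cadomensis:19,(machimosaurus_hugii:23,(steneosaurus_sp:8,steneosaurus_jugleri:8):15):10):15,(goniopholis_sp:7,(sarcosuchus_imperator:35,((borealosuchus_sp:3,borealosuchus_wilsoni:23):15,((crocodylus_niloticus:40,osteolaemus_tetraspis:40):45,((diplocynodon_sp:32,diplocynodon_remensis:5):18,(brachychampsa_montana:7,(allognathosuchus_wartheni:19,(alligator_mississippiensis:68,(protocaiman_peligrensis:3,(caiman_crocodilus:40,(paleosuchus_trigonatus:20,paleosuchus_palpebrosus:20):20):25):3):4):3):5):5):5):55):10):45):35):5):2):2):2):2):2);
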