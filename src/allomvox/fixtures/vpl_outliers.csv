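species,common_name,MaxDF,MeanDF,MinDF,RangeDF,is_vpl,category
Balaenoptera borealis,sei whale,,,U,,True,1
Balaenoptera edeni,Bryde's whale,,,,D,True,3
Balaenoptera physalus,fin whale,U,U,,U,True,1
Berardius arnuxii,Arnoux's beaked whale,,,U,,True,1
Brachyphylla nana,Cuban fruit-eating bat,U,U,U,U,True,1
Caperea marginata,pygmy right whale,D,D,,D,True,3
Halichoerus grypus,grey seal,U,,U,,True,1
Hydrurga leptonyx,leopard seal,U,U,,U,True,1
Hyperoodon ampullatus,northern bottlenose whale,U,,U,,True,1
Inia geoffrensis,Amazon river dolphin,U,U,,U,True,1
Lagenodelphis hosei,Fraser's dolphin,,,U,,True,1
Lagenorhynchus acutus,Atlantic white-sided dolphin,,,U,,True,1
Lagenorhynchus albirostris,white-beaked dolphin,,,U,,True,1
Lagenorhynchus obliquidens,Pacific white-sided dolphin,,,U,,True,1
Lagenorhynchus obscurus,dusky dolphin,,,U,,True,1
Lipotes vexillifer,Baiji dolphin,,,U,D,True,5
Mesoplodon carlhubbsi,Hubbs' beaked whale,U,U,U,U,True,1
Mesoplodon densirostris,Blainville's beaked whale,,,U,,True,1
Mirounga leonina,southern elephant seal,D,D,,,True,3
Neophocaena phocaenoides,finless porpoise,,,U,D,True,5
Phoca vitulina,harbour seal,,U,U,U,True,1
Physeter macrocephalus,sperm whale,U,U,,U,True,1
Pseudorca crassidens,false killer whale,,,U,,True,1
Rhinolophus landeri,Lander's horseshoe bat,U,U,,U,True,1
Rhinolophus megaphyllus,smaller horseshoe bat,,,U,,True,1
Rhinopoma hardwickii,lesser mouse-tailed bat,,,,U,True,1
Sotalia fluviatilis,tucuxi dolphin,,,U,,True,1
Sousa chinensis,Indo-Pacific humpbacked dolphin,,,U,,True,1
Stenella attenuata,pantropical spotted dolphin,,,U,,True,1
Stenella coeruleoalba,striped dolphin,,,U,,True,1
Stenella longirostris,spinner dolphin,,,U,,True,1
Steno bredanensis,rough-toothed dolphin,,,U,,True,1
Tursiops truncatus,bottlenose dolphin,U,U,,U,True,1
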