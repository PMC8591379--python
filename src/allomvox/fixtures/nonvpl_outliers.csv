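species,common_name,MaxDF,MeanDF,MinDF,RangeDF,is_vpl,category
Ailuropoda melanoleuca,giant panda,D,D,,D,False,2
Aotus trivirgatus,three-striped night monkey,D,,,,False,2
Arctocephalus philippii,Juan Fernández fur seal,D,D,,D,False,2
Canis lupus,wolf,D,D,,D,False,2
Cervus elaphus,red deer,D,D,,D,False,2
Dugong dugon,dugong,,,U,,False,4
Eulemur coronatus,crowned lemur,,,D,,False,2
Glaucomys volans,southern flying squirrel,,,U,,False,4
Lophocebus albigena,grey-cheeked mangabey,D,D,,D,False,2
Macaca silenus,lion-tailed macaque,D,D,,D,False,2
Marmota monax,groundhog,,,U,,False,4
Meles meles,European badger,D,D,D,D,False,2
Mus musculus,house mouse,U,U,U,U,False,4
Notomys alexis,spinifex hopping mouse,,,,U,False,4
Notomys fuscus,dusky hopping mouse,,,,U,False,4
Odocoileus virginianus,white-tailed deer,D,D,,D,False,2
Phascolarctos cinereus,koala,,,D,,False,2
Pongo pygmaeus,Bornean orangutan,D,D,,D,False,2
Pseudomys australis,plains rat,,,D,,False,2
Rattus rattus,black rat,,,,U,False,4
Speothos venaticus,bush dog,D,,,,False,2
Spermophilus beldingi,Belding's ground squirrel,,,,D,False,2
Trichechus inunguis,Amazonian manatee,,,U,,False,4
Trichechus manatus,West Indian manatee,,,U,,False,4
Varecia variegata,black-and-white ruffed lemur,D,D,,D,False,2
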