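name,rank,base_age,top_age,parent
Paleozoic,era,416.0,251.0,
Mesozoic,era,251.0,65.5,
Cenozoic,era,65.5,0.0,
Devonian,period,416.0,359.2,Paleozoic
Carboniferous,period,359.2,299.0,Paleozoic
Permian,period,299.0,251.0,Paleozoic
Triassic,period,251.0,199.6,Mesozoic
Jurassic,period,199.6,145.5,Mesozoic
Cretaceous,period,145.5,65.5,Mesozoic
Paleogene,period,65.5,23.03,Cenozoic
Neogene,period,23.03,2.588,Cenozoic
Quaternary,period,2.588,0.0,Cenozoic
Early Devonian,epoch,416.0,397.5,Devonian
Middle Devonian,epoch,397.5,385.3,Devonian
Late Devonian,epoch,385.3,359.2,Devonian
Mississippian,epoch,359.2,318.1,Carboniferous
Pennsylvanian,epoch,318.1,299.0,Carboniferous
Cisuralian,epoch,299.0,270.6,Permian
Guadalupian,epoch,270.6,260.4,Permian
Lopingian,epoch,260.4,251.0,Permian
Early Triassic,epoch,251.0,245.0,Triassic
Middle Triassic,epoch,245.0,228.7,Triassic
Late Triassic,epoch,228.7,199.6,Triassic
Early Jurassic,epoch,199.6,175.6,Jurassic
Middle Jurassic,epoch,175.6,161.2,Jurassic
Late Jurassic,epoch,161.2,145.5,Jurassic
Early Cretaceous,epoch,145.5,99.6,Cretaceous
Late Cretaceous,epoch,99.6,65.5,Cretaceous
Paleocene,epoch,65.5,55.8,Paleogene
Eocene,epoch,55.8,33.9,Paleogene
Oligocene,epoch,33.9,23.03,Paleogene
Miocene,epoch,23.03,5.332,Neogene
Pliocene,epoch,5.332,2.588,Neogene
Pleistocene,epoch,2.588,0.0117,Quaternary
Holocene,epoch,0.0117,0.0,Quaternary
Lochkovian,stage,416.0,411.2,Early Devonian
Pragian,stage,411.2,407.0,Early Devonian
Emsian,stage,407.0,397.5,Early Devonian
Eifelian,stage,397.5,391.8,Middle Devonian
Givetian,stage,391.8,385.3,Middle Devonian
Frasnian,stage,385.3,374.5,Late Devonian
Famennian,stage,374.5,359.2,Late Devonian
Tournaisian,stage,359.2,345.3,Mississippian
Visean,stage,345.3,328.3,Mississippian
Serpukhovian,stage,328.3,318.1,Mississippian
Bashkirian,stage,318.1,311.7,Pennsylvanian
Moscovian,stage,311.7,306.5,Pennsylvanian
Kasimovian,stage,306.5,303.9,Pennsylvanian
Gzhelian,stage,303.9,299.0,Pennsylvanian
Asselian,stage,299.0,294.6,Cisuralian
Sakmarian,stage,294.6,284.4,Cisuralian
Artinskian,stage,284.4,275.6,Cisuralian
Kungurian,stage,275.6,270.6,Cisuralian
Roadian,stage,270.6,268.0,Guadalupian
Wordian,stage,268.0,265.8,Guadalupian
Capitanian,stage,265.8,260.4,Guadalupian
Wuchiapingian,stage,260.4,253.8,Lopingian
Changhsingian,stage,253.8,251.0,Lopingian
Induan,stage,251.0,249.7,Early Triassic
Olenekian,stage,249.7,245.0,Early Triassic
Anisian,stage,245.0,237.0,Middle Triassic
Ladinian,stage,237.0,228.7,Middle Triassic
Carnian,stage,228.7,216.5,Late Triassic
Norian,stage,216.5,203.6,Late Triassic
Rhaetian,stage,203.6,199.6,Late Triassic
Hettangian,stage,199.6,196.5,Early Jurassic
Sinemurian,stage,196.5,189.6,Early Jurassic
Pliensbachian,stage,189.6,183.0,Early Jurassic
Toarcian,stage,183.0,175.6,Early Jurassic
Aalenian,stage,175.6,171.6,Middle Jurassic
Bajocian,stage,171.6,167.7,Middle Jurassic
Bathonian,stage,167.7,164.7,Middle Jurassic
Callovian,stage,164.7,161.2,Middle Jurassic
Oxfordian,stage,161.2,155.7,Late Jurassic
Kimmeridgian,stage,155.7,150.8,Late Jurassic
Tithonian,stage,150.8,145.5,Late Jurassic
Berriasian,stage,145.5,140.2,Early Cretaceous
Valanginian,stage,140.2,136.4,Early Cretaceous
Hauterivian,stage,136.4,130.0,Early Cretaceous
Barremian,stage,130.0,125.0,Early Cretaceous
Aptian,stage,125.0,112.0,Early Cretaceous
Albian,stage,112.0,99.6,Early Cretaceous
Cenomanian,stage,99.6,93.5,Late Cretaceous
Turonian,stage,93.5,89.3,Late Cretaceous
Coniacian,stage,89.3,85.8,Late Cretaceous
Santonian,stage,85.8,83.5,Late Cretaceous
Campanian,stage,83.5,70.6,Late Cretaceous
Maastrichtian,stage,70.6,65.5,Late Cretaceous
Danian,stage,65.5,61.7,Paleocene
Selandian,stage,61.7,58.7,Paleocene
Thanetian,stage,58.7,55.8,Paleocene
Ypresian,stage,55.8,48.6,Eocene
Lutetian,stage,48.6,40.4,Eocene
Bartonian,stage,40.4,37.2,Eocene
Priabonian,stage,37.2,33.9,Eocene
Rupelian,stage,33.9,28.4,Oligocene
Chattian,stage,28.4,23.03,Oligocene
Aquitanian,stage,23.03,20.43,Miocene
Burdigalian,stage,20.43,15.97,Miocene
Langhian,stage,15.97,13.65,Miocene
Serravallian,stage,13.65,11.608,Miocene
Tortonian,stage,11.608,7.246,Miocene
Messinian,stage,7.246,5.332,Miocene
Zanclean,stage,5.332,3.6,Pliocene
Piacenzian,stage,3.6,2.588,Pliocene
Gelasian,stage,2.588,1.806,Pleistocene
Calabrian,stage,1.806,0.781,Pleistocene
Ionian,stage,0.781,0.126,Pleistocene
Tarantian,stage,0.126,0.0117,Pleistocene
Recent,stage,0.0117,0.0,Holocene
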