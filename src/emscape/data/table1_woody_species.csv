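family,species,growth_form,origin,priority,dispersal,AF_total,AF_adult,AF_juvenile
Sapindaceae,Allophylus edulis,tree,native,0,unknown,31,28,30
Rhamnaceae,Scutia buxifolia,tree,native,0,unknown,30,26,22
Myrtaceae,Blepharocalyx salicifolius,tree,native,0,unknown,29,20,28
Celastraceae,Maytenus ilicifolia,tree,native,0,unknown,21,1,21
Cannabaceae,Celtis tala,tree,native,0,unknown,19,10,18
Euphorbiaceae,Sebastiania brasiliensis,tree,native,0,unknown,18,16,15
Myrtaceae,Myrcianthes cisplatensis,tree,native,0,unknown,18,16,11
Thymelaeaceae,Daphnopsis racemosa,shrub,native,0,unknown,18,1,18
Euphorbiaceae,Sebastiania commersoniana,tree,native,0,unknown,17,16,16
Sapotaceae,Pouteria salicifolia,tree,native,0,unknown,17,15,13
Myrtaceae,Eugenia uniflora,tree,native,0,unknown,16,12,16
Myrtaceae,Myrrhinium atropurpureum,tree,native,0,unknown,14,8,8
Anacardiaceae,Lithraea brasiliensis,tree,native,0,unknown,12,11,8
Primulaceae,Myrsine laetevirens,tree,native,0,unknown,11,9,10
Anacardiaceae,Schinus longifolia,tree,native,0,unknown,11,8,6
Arecaceae,Syagrus romanzoffiana,tree,native,0,unknown,11,3,10
Myrtaceae,Eugenia uruguayensis,tree,native,0,unknown,10,10,9
Verbenaceae,Citharexylum montevidense,tree,native,0,unknown,9,5,9
Cannabaceae,Celtis iguanaea,shrub,native,0,unknown,8,0,8
Smilacaceae,Smilax campestris,liana,native,0,unknown,8,0,8
Fabaceae,Calliandra tweedii,shrub,native,0,unknown,7,1,7
Lythraceae,Heimia salicifolia,shrub,native,0,unknown,7,0,7
Fabaceae,Erythrina crista-galli,tree,native,0,unknown,6,6,3
Loranthaceae,Tripodanthus acutifolius,mistletoe,native,0,unknown,6,6,0
Lauraceae,Ocotea acutifolia,tree,native,0,unknown,6,4,5
Oleaceae,Ligustrum lucidum,tree,exotic,0,unknown,6,4,4
Myrtaceae,Myrcianthes pungens,tree,native,0,unknown,6,4,4
Berberidaceae,Berberis laurina,shrub,native,0,unknown,6,2,5
Rubiaceae,Guettarda uruguensis,shrub,native,0,unknown,5,4,5
Salicaceae,Salix humboldtiana,tree,native,0,unknown,5,4,3
Sapindaceae,Cupania vernalis,tree,native,0,unknown,5,3,5
Salicaceae,Xylosma tweediana,tree,native,0,unknown,5,2,4
Fabaceae,Gleditsia triacanthos,tree,exotic,0,unknown,4,3,4
Lamiaceae,Vitex megapotamica,tree,native,0,unknown,4,3,4
Malvaceae,Luehea divaricate,tree,native,0,unknown,4,3,3
Lauraceae,Nectandra megapotamica,tree,native,0,unknown,4,2,4
Verbenaceae,Aloysia gratissima,shrub,native,0,unknown,4,1,4
Fabaceae,Acacia caven,tree,native,0,unknown,3,3,2
Fabaceae,Vachellia caven,shrub,native,0,unknown,3,3,2
Quillajaceae,Quillaja brasiliensis,tree,native,0,unknown,3,2,3
Polygonaceae,Ruprechtia salicifolia,tree,native,0,unknown,3,2,3
Oleaceae,Ligustrum sinense,tree,exotic,0,unknown,3,2,3
Sapindaceae,Matayba elaeagnoides,tree,native,0,unknown,3,2,2
Lauraceae,Ocotea puberula,tree,native,0,unknown,3,2,2
Styracaceae,Styrax leprosus,tree,native,0,unknown,3,2,2
Primulaceae,Myrsine coriacea,tree,native,0,unknown,3,1,3
Polygonaceae,Ruprechtia laxiflora,shrub,native,0,unknown,3,1,3
Rosaceae,Prunus subcoriacea,tree,native,0,unknown,3,1,2
Fabaceae,Acacia bonariensis,tree,native,0,unknown,3,0,3
Rutaceae,Zanthoxylum rhoifolium,tree,native,0,unknown,3,0,3
Primulaceae,Myrsine parvula,tree,native,0,unknown,2,2,2
Fabaceae,Parapiptadenia rigida,tree,native,0,unknown,2,2,2
Anacardiaceae,Schinus mole,tree,native,0,unknown,2,2,2
Anacardiaceae,Lithraea molleoides,tree,native,0,unknown,2,2,0
Anacardiaceae,Schinus lentiscifolius,tree,native,0,unknown,2,2,0
Salicaceae,Azara uruguayensis,tree,native,0,unknown,2,1,2
Rhamnaceae,Colletia paradoxa,shrub,native,0,unknown,2,1,2
Santalaceae,Jodina rhombifolia,tree,native,0,unknown,2,1,2
Primulaceae,Myrsine venosa,tree,native,0,unknown,2,1,2
Aquifoliaceae,Ilex paraguariensis,tree,native,1,unknown,2,1,1
Myrtaceae,Myrceugenia glaucescens,tree,native,0,unknown,2,1,1
Salicaceae,Casearia decandra,tree,native,1,unknown,2,0,2
Rubiaceae,Psychotria carthagenensis,shrub,native,0,unknown,2,0,2
Fabaceae,Senna corymbose,tree,native,0,unknown,2,0,2
Symplocaceae,Symplocos uniflora,tree,native,0,unknown,2,0,2
Myrtaceae,Calyptranthes concinna,tree,native,0,unknown,1,1,1
Salicaceae,Casearia sylvestris,tree,native,0,unknown,1,1,1
Rubiaceae,Cephalanthus glabratus,shrub,native,0,unknown,1,1,1
Boraginaceae,Cordia americana,tree,native,0,unknown,1,1,1
Asteraceae,Gochnatia polymorpha,tree,native,0,unknown,1,1,1
Moraceae,Morus alba,tree,exotic,0,unknown,1,1,1
Myrtaceae,Myrcia palustris,tree,native,0,unknown,1,1,1
Phyllanthaceae,Phyllanthus sellowianus,shrub,native,0,unknown,1,1,1
Fabaceae,Prosopis affinis,tree,native,1,unknown,1,1,1
Myrtaceae,Acca sellowiana,tree,native,0,unknown,1,1,0
Fabaceae,Bauhinia forficate,tree,native,0,unknown,1,1,0
Arecaceae,Butia odorata,tree,native,1,unknown,1,1,0
Cardiopteridaceae,Citronella gongonha,tree,native,0,unknown,1,1,0
Escalloniaceae,Escallonia bifida,tree,native,0,unknown,1,1,0
Bignoniaceae,Handroanthus impetiginosus,tree,native,0,unknown,1,1,0
Phytolaccaceae,Phytolacca dioica,tree,native,0,unknown,1,1,0
Euphorbiaceae,Sapium haematospermum,tree,native,0,unknown,1,1,0
Anacardiaceae,Schinus engleri,shrub,native,0,unknown,1,1,0
Rutaceae,Zanthoxylum fagara,tree,native,0,unknown,1,1,0
Euphorbiaceae,Actinostemon concolor,tree,native,1,unknown,1,0,1
Arecaceae,Butia yatay,tree,native,0,unknown,1,0,1
Cannabaceae,Celtis ehrenbergiana,shrub,native,0,unknown,1,0,1
Solanaceae,Cestrum parqui,shrub,native,0,unknown,1,0,1
Sapotaceae,Chrysophyllum gonocarpum,tree,native,0,unknown,1,0,1
Cardiopteridaceae,Citronella paniculate,tree,native,0,unknown,1,0,1
Rhamnaceae,Discaria americana,shrub,native,0,unknown,1,0,1
Celastraceae,Maytenus dasyclados,tree,native,1,unknown,1,0,1
Meliaceae,Melia azedarach,tree,exotic,0,unknown,1,0,1
Phytolaccaceae,Phytolacca americana,shrub,native,1,unknown,1,0,1
Rutaceae,Poncirus trifoliata,tree,exotic,0,unknown,1,0,1
Myrtaceae,Psidium luridum,shrub,native,0,unknown,1,0,1
Myrtaceae,Psidium salutare,shrub,native,0,unknown,1,0,1
Rosaceae,Pyracantha coccinea,shrub,exotic,0,unknown,1,0,1
Solanaceae,Solanum mauritianum,tree,native,0,unknown,1,0,1
Solanaceae,Vassobia breviflora,tree,native,0,unknown,1,0,1
Salicaceae,Xylosma schroederi,tree,native,1,unknown,1,0,1
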