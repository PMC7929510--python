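species_id,common_name,scientific_name,n_global,n_sites,n_birds,pct_pop,pct_year_known,pct_year_unknown,biennial
DIOAMS,Amsterdam albatross,Diomedea amsterdamensis,90,1,74,100,100,0,True
DIOANT,Antipodean albatross,Diomedea antipodensis,14864,2,211,100,100,0,True
DIODAB,Tristan albatross,Diomedea dabbenena,2218,1,52,100,100,0,True
DIOEXU,Wandering albatross,Diomedea exulans,18568,5,977,100,100,0,True
DIOSAN,Northern royal albatross,Diomedea sanfordi,10270,2,75,100,92,8,True
PHOALB,Short-tailed albatross,Phoebastria albatrus,2600,1,32,78,52,48,False
PHOIMM,Laysan albatross,Phoebastria immutabilis,1333316,1,208,100,100,0,False
PHOIRR,Waved albatross,Phoebastria irrorata,16942,1,54,100,42,58,False
PHONIG,Black-footed albatross,Phoebastria nigripes,140072,1,160,96,96,4,False
PHEFUS,Sooty albatross,Phoebetria fusca,24192,4,121,100,100,0,True
PHEPAL,Light-mantled albatross,Phoebetria palpebrata,41046,5,73,65,58,42,True
THABUL,Buller's albatross,Thalassarche bulleri,65402,1,115,44,44,56,False
THACAR,Indian yellow-nosed albatross,Thalassarche carteri,64414,2,184,87,63,37,False
THACAU,Shy albatross,Thalassarche cauta,29368,1,143,100,83,17,False
THACHL,Atlantic yellow-nosed albatross,Thalassarche chlororhynchos,67300,1,45,100,92,8,False
THACHR,Gray-headed albatross,Thalassarche chrysostoma,165854,5,232,85,57,43,True
THAERE,Chatham albatross,Thalassarche eremita,10592,1,50,100,92,8,False
THAIMP,Campbell albatross,Thalassarche impavida,43296,1,81,100,92,8,False
THAMEL,Black-browed albatross,Thalassarche melanophris,1374890,5,803,88,86,14,False
THASAL,Salvin's albatross,Thalassarche salvini,82426,1,22,3,3,97,False
THASTE,White-capped albatross,Thalassarche steadi,191834,1,38,100,100,0,False
ARDBUL,Buller's shearwater,Ardenna bulleri,700000,1,8,100,100,0,False
ARDCAR,Flesh-footed shearwater,Ardenna carneipes,148000,2,91,48,41,59,False
ARDCRE,Pink-footed shearwater,Ardenna creatopus,67040,1,102,100,92,8,False
ARDGRA,Great shearwater,Ardenna gravis,5000000,1,72,100,100,0,False
ARDGRI,Sooty shearwater,Ardenna grisea,20000000,2,54,46,45,55,False
ARDPAC,Wedge-tailed shearwater,Ardenna pacifica,5200000,4,56,58,49,51,False
ARDTEN,Short-tailed shearwater,Ardenna tenuirostris,23000000,1,16,78,72,28,False
CALBOR,Cory's shearwater,Calonectris borealis,423672,4,514,98,90,10,False
CALDIO,Scopoli's shearwater,Calonectris diomedea,327250,4,228,95,80,20,False
CALEDW,Cape Verde shearwater,Calonectris edwardsii,26228,1,19,100,83,17,False
CALLEU,Streaked shearwater,Calonectris leucomelas,3000000,2,104,59,54,46,False
MACGIG,Southern giant petrel,Macronectes giganteus,95406,5,243,25,19,81,False
MACHAL,Northern giant petrel,Macronectes halli,21382,5,227,81,59,41,False
PROAEQ,White-chinned petrel,Procellaria aequinoctialis,2405136,4,133,80,68,32,False
PROCIN,Gray petrel,Procellaria cinerea,151132,4,61,98,89,11,False
PROCON,Spectacled petrel,Procellaria conspicillata,28800,1,8,100,50,50,False
PROPAR,Black petrel,Procellaria parkinsoni,3000,1,61,100,92,8,False
PROWES,Westland petrel,Procellaria westlandica,5654,1,28,100,92,8,False
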