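species,family,n_female,n_male,c1_female_pg,c1_male_pg,gc_percent,male_2n,sex_system,karyotype_from_congener
Bryodemella tuberculata,Acrididae,2,0,21.92,,42.05,22,XX_X0,false
Calliptamus italicus,Acrididae,2,1,11.68,10.91,42.66,22,XX_X0,true
Euthystira brachyptera,Acrididae,2,0,17.95,,41.51,16,XX_X0,false
Gomphocerippus rufus,Acrididae,2,0,13.18,,41.53,16,XX_X0,false
Chorthippus albomarginatus,Acrididae,1,1,11.88,11.79,41.20,16,XX_X0,false
Chorthippus apricarius,Acrididae,2,1,12.52,11.92,40.84,16,XX_X0,true
Chorthippus biguttulus,Acrididae,0,1,,10.99,41.80,16,XX_X0,false
Chorthippus brunneus,Acrididae,0,1,,10.47,41.17,16,XX_X0,false
Chorthippus dorsatus,Acrididae,2,1,12.59,12.80,41.39,16,XX_X0,false
Chorthippus mollis,Acrididae,0,1,,11.58,41.50,16,XX_X0,true
Chorthippus pullus,Acrididae,1,0,13.44,,41.32,16,XX_X0,true
Chorthippus vagans,Acrididae,2,0,11.11,,41.30,16,XX_X0,false
Chrysochraon dispar,Acrididae,1,1,19.43,18.76,41.43,16,XX_X0,false
Locusta migratoria,Acrididae,0,1,,7.62,41.52,22,XX_X0,false
Myrmeleotettix maculatus,Acrididae,2,0,11.83,,41.40,16,XX_X0,false
Oedipoda caerulescens,Acrididae,2,0,14.13,,42.13,22,XX_X0,false
Omocestus haemorrhoidalis,Acrididae,1,1,12.83,12.14,41.00,16,XX_X0,false
Omocestus viridulus,Acrididae,1,1,14.03,13.28,41.11,16,XX_X0,false
Pseudochorthippus montanus,Acrididae,1,1,13.12,12.42,41.22,16,XX_X0,true
Pseudochorthippus parallelus,Acrididae,2,1,13.14,12.67,41.83,16,XX_X0,false
Psophus stridulus,Acrididae,0,1,,16.44,41.95,22,XX_X0,false
Schistocerca gregaria,Acrididae,1,1,10.68,10.36,43.40,22,XX_X0,false
Stenobothrus lineatus,Acrididae,1,1,14.00,13.63,41.25,16,XX_X0,false
Stenobothrus nigromaculatus,Acrididae,1,1,13.18,12.48,41.05,16,XX_X0,true
Stenobothrus stigmaticus,Acrididae,1,1,11.91,11.21,41.24,16,XX_X0,true
Stethophyma grossum,Acrididae,1,0,18.51,,42.56,22,XX_X0,false
Acheta domesticus,Gryllidae,1,1,2.88,2.63,39.13,10,XX_X0,false
Gryllus assimilis,Gryllidae,1,1,2.24,2.09,38.58,28,XX_X0,false
Gryllus bimaculatus,Gryllidae,1,1,2.22,1.98,38.83,28,XX_X0,false
Gryllus campestris,Gryllidae,1,1,2.23,2.08,39.02,28,XX_X0,false
Nemobius sylvestris,Gryllidae,1,0,2.56,,36.41,16,XX_X0,false
Oecanthus pellucens,Gryllidae,1,1,1.44,1.37,39.97,18,XX_XY,false
Tetrix subulata,Tetrigidae,0,1,,2.22,35.62,12,XX_X0,false
Tetrix tuerki,Tetrigidae,2,0,2.37,,36.08,12,XX_X0,true
Tetrix undulata,Tetrigidae,1,1,2.36,2.18,35.84,12,XX_X0,false
Bicolorana bicolor,Tettigoniidae,1,1,8.05,6.99,39.68,30,XX_X0,false
Conocephalus dorsalis,Tettigoniidae,0,1,,3.52,39.32,32,XX_X0,false
Conocephalus fuscus,Tettigoniidae,1,1,4.42,3.79,39.57,32,XX_X0,true
Decticus verrucivorus,Tettigoniidae,2,2,8.21,7.34,41.01,30,XX_X0,false
Leptophyes punctatissima,Tettigoniidae,1,3,7.98,6.81,41.03,30,XX_X0,false
Meconema meridionale,Tettigoniidae,1,1,10.69,9.90,41.23,26,XX_X0,true
Meconema thalassinum,Tettigoniidae,2,0,12.72,,40.85,26,XX_X0,false
Metrioptera brachyptera,Tettigoniidae,1,1,8.78,7.97,39.93,30,XX_X0,false
Phaneroptera falcata,Tettigoniidae,1,1,7.25,6.08,38.78,26,XX_X0,false
Pholidoptera griseoaptera,Tettigoniidae,2,2,7.11,6.30,40.73,30,XX_X0,false
Pholidoptera littoralis,Tettigoniidae,1,0,7.69,,40.20,30,XX_X0,true
Platycleis albopunctata,Tettigoniidae,2,2,6.54,5.74,39.51,30,XX_X0,true
Roeseliana roeselii,Tettigoniidae,1,3,8.30,7.70,40.30,30,XX_X0,false
Tettigonia cantans,Tettigoniidae,1,1,7.16,6.34,40.89,28,XX_X0,false
Tettigonia viridissima,Tettigoniidae,0,2,,5.69,42.88,28,XX_X0,false
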