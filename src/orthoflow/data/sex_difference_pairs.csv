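species,family,c1_female_pg,c1_male_pg,provenance
Gomphocerippus rufus,Acrididae,13.18,10.66,CROSS_STUDY
Chorthippus vagans,Acrididae,11.11,8.68,CROSS_METHOD
Pseudochorthippus parallelus,Acrididae,13.14,10.89,SAME_STUDY
Schistocerca gregaria,Acrididae,10.68,8.55,CROSS_STUDY
Chorthippus dorsatus,Acrididae,12.59,12.80,SAME_STUDY
Myrmeleotettix maculatus,Acrididae,11.83,12.14,CROSS_METHOD
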