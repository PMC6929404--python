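label,group,n_case,n_control,maf,or,or_allele,platform
Miyashita 2013 (Japanese),east_asian,1008,1016,0.33,1.11,C,Affymetrix GeneChip
Miyashita 2013 (Koreans),east_asian,339,1129,0.36,0.97,C,TaqMan
Xiao 2015,east_asian,459,751,0.37,1.07,C,iPLEX
Huang 2016,east_asian,39,56,0.32,1.04,C,PCR
Jiao 2015,east_asian,229,318,0.36,0.70,C,PCR-RFLP
Liao 2014,east_asian,535,1801,0.37,1.04,C,TaqMan
Tan 2013,east_asian,612,612,0.34,0.66,C,TaqMan
Ohara 2012,east_asian,825,2933,0.32,1.44,C,PCR-RFLP
Li 2015,east_asian,420,441,0.38,2.08,C,PCR-RFLP
Wang 2014 (Southwest),east_asian,333,334,0.36,1.24,C,PCR-RFLP
Wang 2014 (East),east_asian,415,426,0.35,1.08,C,PCR-RFLP
Carrasquillo 2011 (Autopsy),caucasian,296,95,0.30,0.95,T,TaqMan
Carrasquillo 2011 (Jacksonville),caucasian,487,949,0.29,1.08,T,TaqMan
Carrasquillo 2011 (Norway),caucasian,340,550,0.31,1.00,T,TaqMan
Carrasquillo 2011 (Rochester),caucasian,310,1619,0.27,0.79,T,TaqMan
Carrasquillo 2011 (Southampton),caucasian,35,128,0.32,0.94,T,TaqMan
Carrasquillo 2011 (Bristol),caucasian,135,32,0.27,1.12,T,TaqMan
Carrasquillo 2011 (Leeds),caucasian,113,272,0.29,0.94,T,TaqMan
Carrasquillo 2011 (Man/Notts),caucasian,173,84,0.35,0.99,T,TaqMan
Carrasquillo 2011 (NCRAD),caucasian,690,202,0.30,1.00,T,TaqMan
Carrasquillo 2011 (Oxford),caucasian,98,203,0.31,0.89,T,TaqMan
Carrasquillo 2011 (Poland),caucasian,468,180,0.28,1.00,T,TaqMan
Lambert 2011 (Finland),caucasian,563,529,0.24,0.90,T,TaqMan
Lambert 2011 (Italy),caucasian,1460,1265,0.28,0.89,T,TaqMan
Lambert 2011 (Spain),caucasian,726,829,0.29,0.53,T,TaqMan
Harold 2009 (Ireland),caucasian,2227,4697,0.29,0.85,T,Illumina platforms
Harold 2009 (Germany),caucasian,555,824,0.30,0.89,T,Illumina platforms
Harold 2009 (USA),caucasian,551,929,0.29,1.00,T,Illumina platforms
Ramos 2016,caucasian,82,159,0.34,0.98,T,PCR-RFLP
Gharesouran 2014,caucasian,160,163,0.09,0.82,T,PCR-RFLP
Hu 2011,caucasian,1034,1186,0.30,0.88,T,"Illumina 610Quad, HumanHap550"
Carrasquillo 2014,caucasian,54,2397,0.27,0.95,T,TaqMan
Seshadri 2010 (White),caucasian,3006,14642,0.29,0.93,T,"Various Illumina chips, Affymetrix GeneChip"
Seshadri 2010 (France),caucasian,2032,5328,0.29,0.84,T,Illumina Human 610Quad
Seshadri 2010 (Spain),caucasian,1140,1209,0.28,0.88,T,PCR-RFLP
Nizamutdinov 2013,caucasian,166,128,0.33,0.90,T,Biochip
Moreno 2017,caucasian,280,357,0.29,1.12,T,PCR-RFLP
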