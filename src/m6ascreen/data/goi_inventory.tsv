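transcript_id	species	goi
TR13281-c0_g1_i1	Alexandrium tamutum	ALKBH9B
TR95800-c0_g1_i1	Alexandrium tamutum	ALKBH9B
TR95800-c0_g2_i1	Alexandrium tamutum	ALKBH9B
tri_n_comp20163_c0_seq35	Amphidinium carterae	ALKBH9B
tri_n_comp20163_c0_seq44	Amphidinium carterae	ALKBH9B
tri_n_comp20163_c0_seq46	Amphidinium carterae	ALKBH9B
vo_c3_Locus_29131_Transcript_3/4_Confidence_0.500_Length_4920	Amphidinium carterae	ALKBH9B
TR10254-c0_g1_i1	Alexandrium tamutum	ALKBH9B
SampleTS2_Locus_13766_Transcript_2/4_Confidence_0.400_Length_902	Tetraselmis suecica	ALKBH9B
TR111002-c0_g1_i1	Alexandrium tamutum	ALKBH9B
TR111002-c0_g1_i2	Alexandrium tamutum	ALKBH9B
TR5514-c0_g2_i1	Alexandrium tamutum	ALKBH9B
TR74917-c0_g1_i1	Alexandrium tamutum	ALKBH9B
TR74917-c0_g1_i2	Alexandrium tamutum	ALKBH9B
TR98782-c0_g1_i1	Alexandrium tamutum	ALKBH9B
tri_c_comp46027_c0_seq1	Amphidinium carterae	ALKBH9B
tri_c_comp48811_c0_seq1	Amphidinium carterae	ALKBH9B
vo_c1_Locus_8663_Transcript_1/7_Confidence_0.300_Length_2289	Amphidinium carterae	ALKBH9B
vo_c1_Locus_8663_Transcript_2/7_Confidence_0.600_Length_1953	Amphidinium carterae	ALKBH9B
vo_c1_Locus_8663_Transcript_7/7_Confidence_0.000_Length_2852	Amphidinium carterae	ALKBH9B
vo_c2_Locus_8417_Transcript_1/6_Confidence_0.333_Length_2144	Amphidinium carterae	ALKBH9B
vo_n1_Locus_3421_Transcript_10/10_Confidence_0.100_Length_2245	Amphidinium carterae	ALKBH9B
vo_n1_Locus_3421_Transcript_6/10_Confidence_0.200_Length_2273	Amphidinium carterae	ALKBH9B
TR12427-c0_g1_i1	Cylindrotheca closterium	ALKBH9B
TR12745-c0_g1_i1	Cylindrotheca closterium	ALKBH9B
TR65690-c0_g1_i1	Alexandrium tamutum	ALKBH10B
vo_c2_Locus_19652_Transcript_2/2_Confidence_0.250_Length_1986	Amphidinium carterae	ALKBH10B
TR59452-c0_g1_i1	Alexandrium tamutum	MTB
tri_c_comp49311_c0_seq1	Amphidinium carterae	MTB
TR51739-c0_g1_i1	Alexandrium tamutum	FIP37
TR75118-c0_g1_i1	Alexandrium tamutum	FIP37
tri_n_comp42309_c0_seq1	Amphidinium carterae	FIP37
vo_c1_Locus_4428_Transcript_3/4_Confidence_0.879_Length_868	Amphidinium carterae	FIP37
vo_c3_Locus_26772_Transcript_3/6_Confidence_0.529_Length_887	Amphidinium carterae	FIP37
vo_n1_Locus_16_Transcript_73/225_Confidence_0.003_Length_1180	Amphidinium carterae	FIP37
vo_n2_Locus_4713_Transcript_1/2_Confidence_0.333_Length_891	Amphidinium carterae	FIP37
vo_n3_Locus_21951_Transcript_1/2_Confidence_0.985_Length_839	Amphidinium carterae	FIP37
TR126122-c0_g12_i1	Alexandrium tamutum	FIP37
TR126122-c0_g5_i1	Alexandrium tamutum	FIP37
vo_c3_Locus_6426_Transcript_2/2_Confidence_0.250_Length_1098	Amphidinium carterae	FIP37
vo_n2_Locus_6399_Transcript_2/2_Confidence_0.500_Length_1101	Amphidinium carterae	FIP37
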