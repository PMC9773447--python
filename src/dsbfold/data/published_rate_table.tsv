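group	condition_label	growth_rate	R2	R3	R4_cat1	R45_cat2	R5_cat3	R678_cat2	R678_cat3
Chemostat	Chemostat mu=0.5	0.50	0.090	5.388	0.946	0.433	1.297	0.227	0.527
Chemostat	Chemostat mu=0.35	0.35	0.091	4.526	1.093	0.703	2.106	0.673	1.957
Chemostat	Chemostat mu=0.20	0.20	0.040	3.943	0.791	0.535	1.603	0.295	0.886
Chemostat	Chemostat mu=0.12	0.12	0.016	3.181	1.367	0.924	2.770	0.185	0.557
High Growth	LB	1.90	0.228	6.727	1.894	0.337	1.131	0.246	0.584
High Growth	Glycerol + AA		0.199	6.708	2.519	0.471	1.151	0.364	0.371
Stress	pH6 glucose		0.152	7.571	1.599	0.733	2.084	0.227	0.486
Stress	42C glucose		0.048	6.801	1.023	0.370	1.108	0.112	0.240
Stress	Osmotic-stress glucose		0.111	6.637	1.107	0.482	1.518	0.192	0.412
Non-stress sub-optimal	Acetate		0.046	2.758	0.613	0.394	1.181	0.100	0.299
Non-stress sub-optimal	Fructose		0.079	3.230	1.061	0.425	1.149	0.187	0.301
Non-stress sub-optimal	Fumarate		0.065	3.888	0.988	0.556	1.664	0.158	0.406
Non-stress sub-optimal	Galactose		0.044	3.549	0.857	0.562	1.737	0.165	0.505
Non-stress sub-optimal	Glucosamine		0.083	5.008	1.005	0.537	1.608	0.210	0.515
Non-stress sub-optimal	Glucose		0.080	4.309	0.796	0.404	1.092	0.168	0.292
Non-stress sub-optimal	Glycerol		0.048	5.183	0.892	0.486	1.426	0.122	0.321
Non-stress sub-optimal	Mannose		0.072	3.599	0.722	0.320	0.960	0.119	0.321
Non-stress sub-optimal	Pyruvate		0.042	3.351	0.896	0.576	1.726	0.104	0.312
Non-stress sub-optimal	Succinate		0.065	3.925	0.873	0.481	1.440	0.176	0.453
Non-stress sub-optimal	Xylose		0.077	4.400	0.772	0.413	1.059	0.145	0.344
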