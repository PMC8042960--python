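site_id	chrom	start	end	unit	n_units
MS95	chr2	29523420	29523440	A	20
MS101	chr2	29527359	29527377	A	18
MS125	chr2	42481757	42481772	T	15
MS154	chr2	42557759	42557775	T	16
MS165	chr2	47641559	47641586	A	27
MS171	chr2	48033890	48033908	T	18
MS177	chr2	95849361	95849384	T	23
MS210	chr2	215593005	215593025	A	20
MS211	chr2	215593261	215593276	T	15
MS228	chr3	12633424	12633440	T	16
MS230	chr3	12634230	12634252	T	22
MS233	chr3	12635285	12635304	T	19
MS237	chr3	12639509	12639524	T	15
MS245	chr3	12656093	12656105	T	12
MS309	chr3	185787290	185787309	T	19
MS311	chr3	185787762	185787772	T	10
MS331	chr4	25680309	25680328	T	19
MS340	chr4	55598211	55598236	T	25
MS470	chr6	117718359	117718370	T	11
MS478	chr6	117895422	117895436	A	14
MS487	chr6	152421907	152421922	A	15
MS489	chr6	152422169	152422186	T	17
MS525	chr7	13935861	13935873	A	12
MS549	chr7	74608740	74608753	T	13
MS558	chr7	92235951	92235963	T	12
MS569	chr7	116381121	116381137	T	16
MS581	chr7	140480044	140480062	T	18
MS583	chr7	140482263	140482279	A	16
MS598	chr7	140496148	140496164	A	16
MS603	chr7	140498359	140498380	T	21
MS701	chr8	38281180	38281201	A	21
MS752	chr9	133712211	133712233	A	22
MS766	chr9	133721246	133721259	A	13
MS767	chr9	133721468	133721496	TG	14
MS780	chr9	133728557	133728580	T	23
MS790	chr10	8115668	8115686	A	18
MS793	chr10	32315463	32315475	T	12
MS798	chr10	43595836	43595850	T	14
MS875	chr10	89728671	89728692	A	21
MS913	chr10	123336648	123336673	A	25
MS921	chr10	123341275	123341300	A	25
MS974	chr11	102193508	102193534	A	26
MS976	chr11	108114661	108114676	T	15
MS983	chr11	108195976	108195995	T	19
MS990	chr11	118353037	118353053	T	16
MS997	chr11	125490765	125490786	T	21
MS1008	chr12	12024131	12024149	T	18
MS1030	chr12	12032966	12032985	A	19
MS1033	chr12	12036211	12036245	T	34
MS1121	chr14	23652346	23652367	A	21
MS1285	chr17	41256087	41256097	A	10
MS1320	chr18	61873521	61873573	TG	26
MS1396	chr22	23617094	23617118	A	24
MS1398	chr22	23618594	23618609	A	15
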