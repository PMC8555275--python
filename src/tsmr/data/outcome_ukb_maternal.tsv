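rsid	effect_allele	other_allele	eaf	beta	se	n	proxy_for
rs10051765	C	T	0.342	-0.009	0.012	288676
rs10136000	A	G	0.283	-0.006	0.012	288676
rs117885456	A	G	0.087	-0.004	0.012	288676
rs13028225	T	C	0.857	0.006	0.012	288676
rs174547	C	T	0.328	-0.014	0.012	288676
rs2559850	A	G	0.598	-0.014	0.012	288676
rs33972313	C	T	0.968	-0.05	0.012	288676
rs17689159	C	T	0.29	-0.003	0.012	288676	rs56738967
rs6693447	T	G	0.551	0.007	0.012	288676
rs7740812	G	A	0.594	0.012	0.012	288676
rs9895661	T	C	0.817	-0.008	0.013	288676
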