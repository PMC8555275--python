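rsid	effect_allele	other_allele	eaf	beta	se	n	proxy_for
rs10051765	C	T	0.342	-0.036	0.017	260279
rs10136000	A	G	0.283	0.025	0.017	260279
rs117885456	A	G	0.087	-0.005	0.017	260279
rs13028225	T	C	0.857	0.023	0.017	260279
rs174547	C	T	0.328	0.021	0.017	260279
rs2559850	A	G	0.598	-0.005	0.017	260279
rs33972313	C	T	0.968	0.001	0.017	260279
rs17689159	C	T	0.29	0.023	0.017	260279	rs56738967
rs6693447	T	G	0.551	0.015	0.017	260279
rs7740812	G	A	0.594	0.002	0.017	260279
rs9895661	T	C	0.817	-0.025	0.018	260279
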