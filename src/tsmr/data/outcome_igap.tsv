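rsid	effect_allele	other_allele	eaf	beta	se	n	proxy_for
rs10051765	C	T	0.342	-0.0126	0.016	63926
rs10136000	A	G	0.283	-0.0368	0.018	63926
rs117885456	A	G	0.087	-0.0407	0.032	63926
rs13028225	T	C	0.857	0.0071	0.0208	63926
rs174547	C	T	0.328	-0.012	0.0151	63926
rs2559850	A	G	0.598	-0.012	0.015	63926
rs33972313	C	T	0.968	0.0144	0.0428	63926
rs17689159	C	T	0.29	0.0154	0.0166	63926	rs56738967
rs6693447	T	G	0.551	-0.0025	0.0148	63926
rs7740812	G	A	0.594	-0.0137	0.0145	63926
rs9895661	T	C	0.817	-0.0024	0.0192	63926
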