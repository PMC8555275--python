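rsid	effect_allele	other_allele	eaf	beta	se	n	proxy_for
rs10051765	C	T	0.342	0.00272	0.00305	257841
rs10136000	A	G	0.283	-0.00183	0.00320	257841
rs117885456	A	G	0.087	0.00227	0.00497	257841
rs13028225	T	C	0.857	0.00557	0.00412	257841
rs174547	C	T	0.328	0.01375	0.00300	257841
rs2559850	A	G	0.598	-0.00145	0.00290	257841
rs33972313	C	T	0.968	-0.00561	0.00784	257841
rs17689159	C	T	0.29	0.00322	0.00307	257841	rs56738967
rs6693447	T	G	0.551	0.00003	0.00288	257841
rs7740812	G	A	0.594	-0.00565	0.00293	257841
rs9895661	T	C	0.817	-0.00288	0.00382	257841
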