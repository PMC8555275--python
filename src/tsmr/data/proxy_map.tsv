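target_rsid	proxy_rsid	r2	d_prime	target_ea	proxy_ea
rs56738967	rs17689159	1.0	1.0	C	C
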