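rsid_a	rsid_b	r2
rs999737	rs10483813	0.95
rs6678914	rs4245739	0.35
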