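structure_id	chain	ranges	label
7ns0	A	64-371	CtenDNAV_II
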