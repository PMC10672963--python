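metabolite_id	direction	reaction_id	weight	condition
B_c	production	EX_A	0.5	cli
B_c	production	R1	0.5	cli
B_c	consumption	R2	1	cli
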