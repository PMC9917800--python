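label	v_gene_pattern	j_gene	cdr3_aa
iNKT	TRAV11	TRAJ18	CVVGDRGSALGRLHF
MAIT	TRAV1	TRAJ33	CAVRDSNYQLIW
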