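gene_name	allele	segment_type	chain	anchor_codon_start	frame_offset
TRAV1	01	V	TRA	63	0
TRAV3	01	V	TRA	63	0
TRAV6	01	V	TRA	63	0
TRAV9	01	V	TRA	63	0
TRAV11	01	V	TRA	63	0
TRAV12D-1	01	V	TRA	63	0
TRAV14	01	V	TRA	63	0
TRAV16	01	V	TRA	63	0
TRAJ12	01	J	TRA	9	0
TRAJ18	01	J	TRA	9	0
TRAJ22	01	J	TRA	9	0
TRAJ27	01	J	TRA	9	0
TRAJ33	01	J	TRA	9	0
TRAJ40	01	J	TRA	9	0
TRBV1	01	V	TRB	63	0
TRBV2	01	V	TRB	63	0
TRBV13-1	01	V	TRB	63	0
TRBV19	01	V	TRB	63	0
TRBJ1-1	01	J	TRB	9	0
TRBJ1-4	01	J	TRB	9	0
TRBJ2-1	01	J	TRB	9	0
TRBJ2-7	01	J	TRB	9	0
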