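>TRAV1|01|V|TRA
CGCCTTGAGTACTTGCAGAAGACGTGTTGGTCAATAAATAGCTCAACGCCACCTACACTCCGTTGCTTATGC
>TRAV3|01|V|TRA
GTCGTAGCTTCTAATAATCTAACTATACGACTACGCTGCCAAAGTAGACCTCTAAAAACTAAGTGTTATAAC
>TRAV6|01|V|TRA
GCGCGGGATTGCATGAGAACCCACGGGTCGGTGTGTAAAAGGCTTCGCAGCTTAAGAACTATATGTGCTGGA
>TRAV9|01|V|TRA
TGTTCACTCGGGCATCGAGGTTTAAAAGTATTGACCAGGGACTCGACGCCTCGTTGGGCCGTCTGTGTTGGA
>TRAV11|01|V|TRA
CGCGGTCAGTCCGTACCTCATGCACGTCAGACGTCACTGGGGTCGGTACCCGGCTCTGCTCGCTGCGATAGC
>TRAV12D-1|01|V|TRA
AAGCTACCACGTAGCAACAAAATAGTTGCTTTCGTGAGTGTGGGCATAGTCCAACACCCTGAATGCATAGTC
>TRAV14|01|V|TRA
ATAGGGCCCATAATGGCTGTTGCGCGCTCCTTTCAGCGATATGGCGAACGAGGAGACATCCCCTGTAACCGC
>TRAV16|01|V|TRA
GCCACGTATGGATCTGTGTCTCATCTGGTTTCATCTGGAAAAGGCTGGCAGTCCGTAGACGCTTGTAGACCA
>TRAJ12|01|J|TRA
TACTGTCAATTCGGTAAAGGGAGGGGTTACTTTACT
>TRAJ18|01|J|TRA
ATGAGGCTGTTCGGATCGGGTCGGAAGAAGGTGGAC
>TRAJ22|01|J|TRA
AGAGGGGCCTTTGGGAGGAAGGCCTCCCCAACTCCC
>TRAJ27|01|J|TRA
TGGGGTTCGTTCGGGAAACTAAACTATGCCGATGGA
>TRAJ33|01|J|TRA
GGTTTTCGCTGGGGGAGCACCGCAAGCAAGCCTACT
>TRAJ40|01|J|TRA
ACCACCATCTTTGGTCCACTGTTGAACAGCATTCTA
>TRBV1|01|V|TRB
GAGCCAACTAAATGTGTGACTGTCTTGACACAAAAAATTCATCCATGTGCCCCATGCCCAGCGTGCCCAGAA
>TRBV2|01|V|TRB
TTCCACCTACCACTTCTTCATGTCTACCCCTTGAAGTTTCTTACTTGTGCTCGCGCTCGCCCGTGTCATCCC
>TRBV13-1|01|V|TRB
CTTTGGGCAAATACTTTGCGGCCACATGACAGCCTTCTCTGTAGCATCTACAACCCTCTAGAGTGCGCGAAA
>TRBV19|01|V|TRB
GAATTACGAGTAAGGGGATCGCACTCTAAAGCGGGCTTGAGGTATAAGTTGTTCCAAGTTACGTGTGATTTC
>TRBJ1-1|01|J|TRB
AGTAACCTATTTGGCTGTCCTTTCGGTGTGATTTTT
>TRBJ1-4|01|J|TRB
CGGAACACGTTTGGCCCATCTGCATACTTTCGAGAT
>TRBJ2-1|01|J|TRB
CTCTCATCGTTTGGGGCACACTTAATGAACTGGCTG
>TRBJ2-7|01|J|TRB
CTCACGATATTTGGGTTTAAGACTTGGTTCAAAACC
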