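>CC-A1.1 synthetic stand-in control-region sequence (accession EU179436)
CGCCGCTCCAGACAGGTCAGCCTCCGCGGGAAACTATTACATCACCGCACAAGGTGAGCCTAACGACGCG
GAATGACACAGGTCCTCGGGAAATCCCGTGCGTACCTAGTTCCCTGGTGCTCCGTCGCGCACTAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCTTATCCTTGGGAGCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGTCCATTTATTTGACGTAGTCGTCCCATCAGTGGCGA
CTCCATTAAGGGGTTTCCACTTCTTGGTCCTCCATGCCACTCACAGTCAGGGCTCCTTAAGCTACCTTTG
CTCTTAATATCAGCGTATTTGGACAGCGACACGCCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCT
GCGCACGGCGGCAATTTACCTGATGTGACAGAAGGTGATTAGATGCACGTTCCTCACGGGTTCTGTTAGG
GGGCAGCATAGGGCGCCTGTACTCGGCATTACAGGCTACTGACGACATAGGGAAGGGGCTATACCCTATA
CGATTTGCTGGAGGCAGAACCGATCGAAGTCATGTTATCTCGGAGTCTAGAGAAGAACTCACTCGTTACC
TGCTCCTGGAAATCGTTTGACGTGCGTCTACAATCTATTTCGCAGTCGACGCAAAGGAGCTCATTTTTGG
ACAGTTCTGGCTATGTACGTCAATTTGGCTGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGACGCAAGTCGGGATACGCTTACCGTACCAAGCGTGGGATTGGGCTTC
>CC-A2.1 synthetic stand-in control-region sequence (accession EU179445)
CGCCGCACCAGACAGGTCAGCCTCCGCGGGACACTATTACATCACCGCACAAGGTGTGTCTAACGACGCG
GAATGACTCAGGTCCTCGGGAAATCCCGTGCGTACCTAGTTCCCTGGTGCTCCGTCGCGCACTAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCTTATCCTTGGGAGCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGACCATTTATTTGACGTAGTCGTCCCATCAGTGGCGA
CTCCATTAAGGGGTTTCATCTTCTTGGGCCTCCATGCCACTCACAGTCAGTGCTCCTTAAGCTACCTTTG
CTCTTAATATCAGCGTATTTGGACAGCGACACGGCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCT
GCGCACTGCGGCAATTTACCTGATGTGACAGAAGGTGATTAGATGCACGTTCCTTACGGGTTCTGTTAGG
GAGCAGCATAGGGCGCCTGTACTCGGCATTACAGGCTACTGACGACATATGGAAGGGGCTATACCCTATA
CGATTTGCTGGAGGCAGAACCAATCGAAGTCATGTTATCTCGGAGTCTAGTGAAGAACTCACTCGTTACC
TGCTCCTGGAAATCGTTTGACGTGCGTCTACAATCTATTTCGCAGTCGACGCAAAGGAGCTCATTTTTGA
ACAGTTCTGGCTATGTACGTCAATTTGGCTGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGACGCAAGTCGGGATCCGCTTACCGTACTAAGCGTGGGATTGGGCTTC
>CC-A3.1 synthetic stand-in control-region sequence (accession EU179455)
CGCCGCACCAGACTGGTCAGCCTCCGCGGGACACTATTACATCACCGCACAAGGTGTGCCTAACGACGCG
GAATGACACAGGTCCTCGGGAAATCCCGTGCGTACCTAGTTCCCAGGTGCTCCGTCGCGCACTAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCGTATCCTTGGGAGCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGACCATTTATTTGACGTAGTCGTCCCATCAGTAGCGA
CTCCATTAAGGGGTTTTCACTTCTTGGGCCTCCATGCCACTCACAGTCAGGGCTCCTTAAGCTACCTTTG
CTCTTACTATCAGCATATTTGGACAGCGACACGCCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCT
GCGCACGGCGGCAATTTACCTGATGTGACAGAAGGTGATTAGATGCACGTTCCTCACGGGTTCTGTTAGG
GAGCAGCATAGGGCGCCTGTACTCGGCATTACAGGCTACTGACGACATAGGGAAGGGGCAATACCCTATA
CGATTTGCTGGAGGGAGAACCAATCGAAGTCATGTTATCTCGGAGTCTAGTGAAGAACTCACTCGTTACC
TGCTCCTGGAAATCGTTTGACGTGCGTCTACAATCTATTTCGCAGTCGACGCAAAGGAGCTCATTTTTGA
ACAGTTCTGGCTATGTACGTCAATTTGGCTGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGACGCAAGTAGGGATCCGCTTACCGTACCAAGCGTGGGATTGGGCTTC
>CC-A9.1 synthetic stand-in control-region sequence (accession EU179463)
CGCCGCACCAGACAGGTCAGCCTCCGCGGGACACTATTACATCACCGCACAAGGTGAGCCTAACGACGCG
GAATGACACAGGTCCTCGGGAAATCCCGTGCGTACCTAGTTTCCTGGTGCTCCGTCGCGCACTAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCTTATCCTTGGGATCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGACCATTTATTTGACGTAGTCGTCCCATCAGTGGCGA
CTCCATTAAGGGGTTTCCACTTCTTGGGCCTCCATGCCACTCACAGTCAGGGCTCCTTAAGCTACCTTTG
CTCTTAGTATCAGCGTATTTGGACCGCGACACGCCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCA
GCGCACGGCGGCAATTTACCTGATGTGACAGAAGGTGATTAGATGCACGTTCCTCACGGGTTCTGTTAGG
GAGCAGCATAGGGCGCCTGTACTCGGCATTACAGGCTACTGACGACCTAGGGAAGGGGCTATACCCTATA
CGATTTGCTGGAGGCAGACCCAATCGAAGTCATGTTATCTCGGAGTCTAGTGAAGAACTCACTCGTTACC
TGCTCCTGGAAATAGTTTGACGTGCGTCTACAATCTATTTCGCAGTCGACGCAACGGAGCTCATTTTTGA
ACAGTTCTGGCTATGTACGTCAATTTGGCTGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGACGCAAGTCGGGATCCGCTTACCGTACCAAGCGTGGGATTGGGCTTC
>CC-A10.4 synthetic stand-in control-region sequence (accession JQ340912)
CGCCGCACCAGACAGGTCAGCCTCCGCGGGACACTATAACATCACCGCACAAGGTGCGCCTAACGACGCG
GAATGACACAGGTCCTCGGGAAATCCCGTGCGTACCTAGTTCCCTGGTGCTCCGTCGCGCACTAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCTTATCCTTGGGAGCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGACCATTTATTTGACGTAGTCGTCCCATCAGTGGCGA
CTCCATTAAGGGGTTTCCACTTCTTGGGCCTCCATGCCACTCACAGTCAGGGCTCCTTAAGCTACCTTTG
CTCTTAATATCAGCGTATTTGGACAGCGACACGCCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCT
GCGCACGGCGGCAATTTACCTGATTTGACAGAAGGTGATAAGATGCACGTTCCTCACGGGTTCTGTTAGG
GAGCAGCATAGGGCGCCTGTACTCGGCATTACAGGCTACTGACGACATAGAGAAGGGGCTATACCCTATA
CGATTTGCTGGAGGCAGAACCAATCGAAGTCATGTTATCTCGGAGTTTAGTGAAGAACTCACTCGTTACC
TGCTCCTGGAAATCGTTTGACGTGCGTCTACAATCTATTTCGCAGTCGACGCGAAGGAGCTCATTTTTGA
ACAGTTCGGGCTATGTACGTCAATTTGGCCGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGGCGCAAGTCGGGATCCGCTTACCGTACCAAGCGTGGGATTGGGCTTC
>CC-A20.1 synthetic stand-in control-region sequence (accession EU179452)
CGCCGCACCAGACAGGTCAGCCTCCGCGGGGCACTATTACATCACCGCACAAGGTGTGCCTAACGACGCG
GAATGACACAGGTCCTCGGGAAATCCCGTGCGTCCCTACTTCCCTGATGCTCCGTCGCGCACAAAACAGG
CATAGCCAAGGGCCGACGTGTCAAACGCGCTTATCCTTGGGAGCCGCTAGCGCGACTCTGTTAGCCTATC
AACGCCGGCGGTGGACACATCTGGTCCTAGAAGGACCATTTATTTGACGTAGTCGTCCCATCAGTGGCGA
CTCCATTAAGGGGTTTCCACTTCTTGGGCCTCCATGCCACTCACAGTCAGGGCTCCTTAAGCTACCTTTG
CTCTTAATATCAGCGTATTTGGACAACGCCACGCCGCCGGAGATAATGGTATGTCCAGGTGATCCGGGCT
GCGCACGGCGGCAATTTACCTGATGTGACAGAAGGTGATTAGATGCACGTTCCTCACGGGTTCTGTTAGG
GAGCAGCATAGGGCGCCTGTACTCGGAATTACAGGCTACTGACGACATAGGGAAGGGGCTATACCCTATA
CGATTTGCTGGAGGCAGAACCAATCGAAGTCATGTTATCTCGGAGTCTAGTGAAGAACTCACTCGTTACC
TGCTCCTGGAAATCGTTTGACGTGCGTCTACAATCTAGTTCGCAGTCGACGCAAAGGAGCTCATTTTTGA
ACAGTTCTGGCTATGTACGTCAGTTTGGCTGCCATGATTTTCAACGAGCTATACGACCGGTTATCAAGGT
TGGACGCAAGTCGGGATCCGCTTACCGTACCAAGCGTGGGATTGGGCTTC
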