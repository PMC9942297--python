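>NUL0000.c1
ATGGCGCCCTTCCAATACGCCCGGAGAAAGCAGATGGTCTCAGCCTTTTCCGCGGTGAGTGAGTTAAGTAAGGCAGGCGACGAGTGCTCCGTCGTGAAAGCAGCCTATCTATTCTATGGTCCTGAACGATTCTGCCCTTTATTAGTGTCAGCCCGCTCTGCAAGACTATCGTCCCCGCCTCCACCGAAACCAGCACATGGCATTACGCACGTTAAGGGCCTTCTCATAGGCCGCCCGTATAGTATACGCCCTGAGCCGAGTGCCACCCAGCTTTGA
>NUL0001.c1
ATGCGAAGTGTGACTCATTCGACAGGGATGAACCCGGCCTGTTTTCCGCGCCCGACACACACGGCGGCATTTGAGAGCGTTCAATTCCCCCCCGAACTCACTTACATCCGCGGTCGGGTCTCTCCAACAACGAGTTCCTCAGGCACGCGCGTGGGCCTCCATCAACCAGGTCAAATAGCGAAAGTTAGAGCATCGCATGGGCTAAGGATTGGACGAACAGATGATCGTACGGTCCGAGCAAGCAACCTTGGATTACGCTCACTCATCTAG
>NUL0001.c2
ATGAGAACCATTACGTGTTACCGAGAAGTGGTCTTCCGGCAATCTAGATCGTCGGCTAGGCCAGATCACCGCCTCCTGCTGATGCAGATTTGTCCTCTTCGCGAAGTATGCGCCACCCGTGAGCTGAGTGTTCAGCTAGTCGCAACTACTCGAATAAGTCGCATCACTATGTTCAGACTGCCATGGTTGGAACCGCTGCTTTTAATTTTGAGAGTTGATGGACTTCTTTTCTACCAGAGCGCCCAACTCGGAGCTACGGGTAGCCCTATGTTGTCACACACCGAAGCTCCCACATACGGTCTGGTTTTTTAG
>NUL0002.c1
ATGATCGCTACGCTGGGGTGCTTGAGCGGCGTACCGGGCCTGGTCTTTGGTGTTTGTATAATCTTGCAGGTTCTTCCTTTTCTTCACGTTCATAGAATAACATGCTGGCGGGACGTGTCAACATTTATAGGAGATATTCAGGCATTACTGAAGGCCCATATCCCATCGCTCCGAAACCCCTGTTTGAAGTGGTCCAGTGGTCTTAGTCGGGTTAGGATCTGGTACGACACGCGTAGACTAGAGAAAATTGATTATTACATATCGTCGCTTTCCAGATACGTGAAGTATCCTACCACCCCCTCAACGTGTTCACACTTATAG
>NUL0003.c1
ATGAATGCTCGTGCGCAGTCCACCCAGGTGTGCCATTATGGGGTGTCCTCAGTTAAGAGTCGCCTCCTAGCAATGATTCGATATAAAATTGACAAAGAACCAACTGCGCTAAGGAGGCCGAAGTCGGCGAACAACTGGGAATCGACGCTCGAAGCGAAGACCAAGTTTCTTTTGCCGTGTAGGGGCTGGCGGCCGCTCTTACTTTACTCAGAGATGCCCGTAGTCACTTGCTCCTTACAGAGCTTACAGCCTGATATTAAGCTCGAGCCGGGCCATGTGTATGGTTGTATCAGGTCCAATCATAGGGGAAGCGTGTATCTGGAGAAGAAATTGGTATTAAACAAGGATCGGGGCCATCACAGGCGCGTCCTTCGGAGCAAGAATAGCTATTCATACGCTGAACTCTATCCTGCAGACTGA
>NUL0004.c1
ATGCTGTTAGTTAGATTTTGGAGAAGTCAAAAAGACCGTAAACCCAACAGGCAACCTCCTGTGCGTCGCTTTGTCACTCCTTTCTGGGATGTTTTGATATTCTGTTGGACGCACGTCCACCGACTGGGCACAATGCGATGTTATAGGTGTTCCGCACACCACTCCACTACCCTAAGCTTGGAGGGAACGTGCGATCGATGCTCGATTTTGACGAGAACACCGGCTGCCCATCGCATGCTACAAAACACTCGTTATCCTCCCTATGGTATGCAGTCTTATTACTCTCAAGTGGTAATGCGACCAATGGCGAAGCAGTTCTCACACGAGTTTCTTCTAACGCATCCTATCCACAGTCACCGCAATGAGCTAGTACGGGAAGATTACCGAGTTGAACTTTGTGCTGATTCAAGTAAAGTTCAATATAACGAGACCGTACCCTAA
>NUL0004.c2
ATGGACATCTCTCCGTCAGAAGGGCATGCTGGCAACTGCCGTAGGGGTTCAATCAAGTACCGTCATATCGACCTGACAAAAACTTCAAGCCTAGAGGGTGCTGGGGCCTCCGTGTTCCCTAACAGAGGGTGTTTTGCTCAGGGCACTTCTCGGTTTGTCAACAGCACTGAAGGCATTTCCCCCAGAATCCACTGCGCACTCTAA
>NUL0005.c1
ATGTATAAGTCGACCCCACCTCTAAGTTTTAGACCAAGCCAACGGGTTACACCACGCGAGGCAACAAATCCACAGTTTCATAGCGAACTTTGCTATAAAGTTGGGGTGCGCGGCACAGAACACTCATTCGCTCTACGGGCACAGCAGAGCTTCTATACTAGCGGTATGGAAGAAGCTAGGCTCCCTATACACGAAAGTACTTTAAAGGGTGACCCTCGTCTTTTGGGTCGCCATTCATGGGGCTCGAAGACACTAAAATACGCTAAATATCGGCACCGAGGTAGCAGATGTGATGCTTCGACGGGCAAGCATCGCTCCGCAGAGCATGGGCGATACTATGACAGATCTAAATAG
>POS0000.c1
ATGAGGGGCGTAAAGACTAAAAAGTTTGGCGCCCGGGGCCCCCCCCCCGAGAGGCTTACGGGAAGATCTCCCAAGGGAACCCTCCCTGTAAACGGGGGCCCGGCGTCTGAACTGGCCAACAATGACCAGCCAATCCCCCCCCCCTTTTTCCACCCGCCCCCCCGAGGCACACCCAAAAAAACCGTGCTTTATTGCCCGGAGAACGTCAACGTGGACCCCGCCCAACCCCCAACCATCTTCCAGCTGGACCCCATTTTAGGGCTCCCGATCGGCGCCAGGGTTTTTGGCCACGGGAAGGGTAGCAGAAATGCCCAATGTTCGAACCTTGCCCGGGCCGGCGATGACCGGGGGGGGGCAACGCGACTTCTTCGCTTCGGCTTTAGAATGCCCCACCGACCCCCCTTTCCAAATTCAAGCGTTCCCAACACCGCCAGAGGATGA
>POS0000.c2
ATGAGATGTATATTAGAACGGCTTTGCACCAACAGGCCTGCAAGACCCAAGCCCATTTCGTCTGATACTCCCAAGGGCTTACCCCAACTGGTCCCCGACTTCCTCTCCTCTAGGGTGATTGGGGACCTTAAGGGGGGCTTTTGCGACTACGAGCGGAATTTGCCTCACGAGCCGTGTAACCCAATTCCTCCGCCCCCCGGCAAACTCCGTCCCCACATGCCCCGGGGCCTAAAAAACCTGGTGGTTGTTATCCTCCTGGTGGCCTTCGCCCTATTTCTGGCAATAGTGGCCTTTATTTTTACCCTCCCCGGTATGCCTTTGCGAGGCCTTATCGCCCAGGGCGCCCCAAAATCTTTCTACCCCGGCCCCGCCGGCACCGTGATCCTGGTTTAG
>POS0001.c1
ATGGCCAGAACTACCCCCACATTCGTGCATCGCCCCCCCACCGTTAAGGGCAAGCTTAGCGGGCAGTTAGGTAGTGCCCCGGCCAGCCTTTCCCCGAGCCCCCGCCAGGCCCCGCTTCCGGCATGGGTGAATTGGACCAACAAAGTTCCCGCTTTCCAGTCAGTTAACTTTGCGATGTTCTAA
>POS0002.c1
ATGGGCTTGCAGCCGGACCGGGGGGGTAATTGGGTTAAAATGCCCACCCCCTGCGCCGCCCTTCTGCTTGTGCTGGCCATTTTAGTGTTGGCCTTTGCTTTCTTGGTCGCATTAATTCCCGGAAACCCCGCGCGGTTCGGGGACCGGGTGGAAGGCGGTTGGTGTTTAATGCGGGAAGGCTATGGGGGAAACCCCATAAGCTCTTTTGGTGGTTTCCACGGCTCCAACACCGCCGCCCTCCTGTACCTTACCCCGGGCCCAAGGCCATTGGCAGAGCCCAAGTGGCTCCTTCCCCCTCCCCACCCCCCCAACCTGGGGCCGGTGCCCCTGAACGGGAAGGTTTTGGGAAAAGCAACCGGCGAAAAATTTAGGCAGGGGCCGGGCCGAAATGACCCCAAGCCCCTCCAGGTCTGA
>POS0003.c1
ATGATCCAGGGGGGCGCCGTGGTTTTATTGGCTATCGCCGTGCTGTTCCTGGCAGCCTTCTTCCTCTTTCTCGTGGTGGGTCCGCTAGCTGGGGCCCCGGCGCCCATCCGAAACCATACTCAGATTCAGTCTAGATTCCTGAGAACCGACTCTTCTGCCGGATTCTCAGGCCAGGAGTACCACGCTAGCGAGCCGGTTCCCCCTACTCTGGGCCCGAGGCCTTTTTTAATCCGGGACAACTGGCAGTCAAAATTGGGCTTTGCCTCCCCTAACGGCCCTGGGAGGCACGTGGACTTCCCCCAGGCCAGCCTAAAGGAAGGAAACCGGTCTGAACTGGGCCCCCTGTTGGCGCTGTTAAGCCCCCGTTTAGCCCCCAGGGGCCCCGCCCAAGGAGTGCTGGGCCTGGGGGGCCCCCCGGGTTTCCTAAGCCCGAACCACAATGCCACGCCCCCCTTCAAACTGTCTCGCCGTGTAGTTTGCTCAAACGGGTGCCGTCTCTAA
>POS0003.c2
ATGGCCTTTAGGACCGACGGCGTCGGGGACCCCTCAGTGAACAGAGCCCTGTTTAGACTGGCCCCGGAGCACCATGGGCGAGCAAGCCTCCCCGGCCCCTTCGGCGGGGTTTCCGTCTACCCCCTACGTCCCAACGGCTCCACCAGAGCCGTCTTCCTCCTCGTGGTGGCCTTAGTGGTCGTGTTGGCCCTCTTCTTTATCGTGTTCGTGGGGTTCGGAACCTTAACCCTGGTCCCGGGGGCGCCCCCTAAGGCCCATTTTTGTAGAAAACCGAGCACGCAAAACTCAATGCGCCCCCACGTCGACGCCATTGAGCTTGTCCCCTAA
>POS0004.c1
ATGTTCTCGCCCCCGCTTGCCCCTTTCCCCGACCCAGCTTTTCTCGCGTTCTTCGTGGTGTTAGTGGTTGCCCTTGCCTTTTTACTAATCGCAATCCTCCCATCCCCCCAAGGGGCCGACCCCGGCTATACACGGGGCTCGTGGCCCCCGGGCCCGGGCCAGATCAGGAGCTACCTACCCGCCGAGCCCAAAAAGAATGCGGGTTTCATCGGGGCTTCAGGAGTTTTGCCCTGTAGCTGGAAGGGCCCCAACCCCAGCTGGTGGAGAGCCGGGCAGGGCCAAGAGGGCCTTGGCCGGCGTTACGGCAGGAAGCCCGCCCGGTAA
>POS0004.c2
ATGGACGGATTGCCCCACCCCCTGAGCCATCCGGTGGAAAAAAGTCCTGTCTGCTTGCCCAACACGAACACCTTTTTCGCGACCGGCGTCCCCCCCGACCCCCCAGACAACCTTGAGACCCTCCAAAGCTTCAGGGGCGAGATAACCCCCGCCCAGGACAAAAAATGGGCCCTCAACCGAGTCCCCTGGGGGGACTACCTAACCCTCGCCGAACCCGCACTGGTGGGGGAAAGCCGGGGCGAGGGGGGTTTTTGCTCAGCCCACGGCCCCGCACCGGGGCCGCCCGTATTCTTACTTTTGCTGATCTTCCTGCTGGCCGTGTTCATCGCCGCTTTTTTCCTTTTCGCCCTATGA
>POS0005.c1
ATGCAGGCATGGAACGGGAGCCCTGTGAAGAGCAGTAAGGGGGCCCCCCCCATCGCCCAGAGGAGACCCCAGGGGGCCGGTGGGGGGGAAACCCGCTTGCGGCCCGCCAGCCCCCAAACCCTTAAGATCGTATTCGCAGCCCTTGCCGTGGTGGTAGTGTTGTTTTTTTTCGCCGCCGCCGTTGCCGTGGAGTTTTTCCCCACGTTCAACCCCGGCTGGTGA
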