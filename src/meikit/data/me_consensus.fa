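>ALU
AGGCGTGCATGCGAAGCACAATGAGTCATAACCCTTAGACCAAAGATGAGATATGCATGAACTTATCTTC
GTCCATCAATCTTGCTATACGATGGTGAAATTGGTGGGGGCACTGCGATCGAAGTGGCGCGGCCGACCCT
AGGAAGGCATAAACTTGAGGCACGATTTGTTAGCGGGTATGCGCGTTTGGCCATGTTCCGTGGTAATTTT
CCTTTTTGTGAACTTCTTGGGGGACGATCCACTCCCTTTGTTTACATCACGTCGCCCGCTACCACCGTAA
ACACTCTTCTAACGGTTCAG
>LINE1
ACGTGGAATCCATTCACTACGTCGCGTTGGGTGGGCGCCCGTCCCACTTACCCCGACCGTGAGTAAGATT
CATCTTTTTCATAAGTGCATTTTCCGTGTCTAAATTGTCCATGAGGGCCTAGGACGTCTAAGCACCCTTC
CAAATGATAGGAGCTATTGGACCATCTAGCCCGTGCGTGGACTATTGGTGTGATCTGGACCTTTTGTGTA
AACGATCCGTTAACCAATTGATCCTGCCGCACGATGCTGGCTCTCAAGGACCTTTGGGTGTGGGAACAAG
ATCAGGTTAATTCGGGGTAGCGCACAATGCATTACGAGACGAGTCCTTCTCCCTGTAATGACTATTCACG
AGGTGCATTCTGAAATAAATATGTACACACGCCGAGTTGGCTAGCCCCTACACCTTACAAATATATTTGG
GACCAGGCGACTCCAAGAGACTGGAAAAATGTCGAGGCGGAGTTGAAGGGCTGCGGGTCCCTACAGGGGC
GGGCTTGGAAAAACACGTACTCTGGCTCGACGTTCGGTTAGTGCGTACAACGCTCTTCCACAACTAAGGA
GCAAACAGGGGATCCCTTCTTTACGGGGCACATCGCTCGGGCGATCAAGACCATTCAGGGAGCCGTCGCC
GAGCCAGGTCGATCTGCGTTTCACGTAAGGACCGGTAAAAGGTGCGGGGGTTGGAGTATCGATACACCCT
ATATACCGCTTGAATATCTTTGTCCTACCTAAAGTGTTATCTGCGAAGGGAAGGTAACCGGCCCGATGAC
TCAAACCTATGCTGCCGTACGAACTTCGAGAAGGCTCCGAATAGGTATTCTATCCCTTCGCCTGAAACAG
AGCTCCAGTCTAGAGGTGCGCCCGGGAGTTGGATTTACGCCATGCGCTATATAGATAGTACCAGTATTAT
CATGGGTAATATTATCGTATGTGCAGCGCCAATTCTCGTCCGTATAGTGTGGCCTGATAGATAGAGGATT
GCGGACCACCACAGATCTTTATGAACTAACGCATCGATGCACATCCTTCTCACTATGTAGTTAGATCTCG
ACCCTCCATTGCGTCGCCAAAGCCTCACGGCCCGGCCCGTGGTTACTACGCGGGATGAGTCGCGATGAGC
CGACACGATTCACTGCTCATGTTAGAAGATTGTAGACGGAGCCTATCGCTGAGGTGTACCATCGAGTACT
AGATTCCGCATACAATAGACATATGAGCCTATTTTTGGTTCCTATATGATGTCCCGTACGTCGGGAGGGA
TCTCCCCAGACCACAGCATCCCCTAGCCTTCTCACGACCTGTGGTATGATCCTCACGGTCGTGTCGAAGT
TAAACAGATACCGAGCTAGATTTCTAGTACTAAGGTTGTTGTCCGATCTCACAGTCATGATTGTATAATC
ATTAAGCCCAGATCTACTCGTACGGGACTCTCGTTCTGTGGCTGAGACTGTTCCTGGTCAAGACTGGTCC
GTAGCGCAAGACACCATTGAGTAAAGGGACATTACTTATACCGTTTGTCGCGGAGGAACCAAGATAACCC
GTAGACTGACGTCAGCAGTGGGTCGTGCTCTAGCCTCAATTCAGTCGACCTAGACGCGATGCCGTACTGA
CCCGACAGCAGCTGGTTCCTTGTGGTTGCTCCCAGTATATGCCCATATGATGTAACAGATCACGGACGAT
GCAGCGGGTATCTTCGCTTAGCTCGGTCCTCGTTCACACGGGTGGTCCATCACTAACTTAGTGCTATTTT
TACGTAGTTGTAAGAATATCGTCAACGACGTATGAGCTCGTTGGACAGCCTTCACTACGATCAGACAACA
TCTATTGTATTTGAAGTCTAGATAAGGCAGATGCTACCGTCGGTGCAAGCTCTCTTTAGCAATACGTCCG
GCGGTGCGTCTCATGTGGCGACGCGGCAAAACAAACACTAATGAAGAAGGCTATGGCACCTTTTAGGGCC
GCATGATGTACAGCACTGGATTAGCCTCAGGTTTGCCCGACGCTAAGAATCGCGACCTCCATTGACGACG
GCGGCACTCGATTCTCAACGCCCTCAAGTAAATCACGTCTCACACACATCTCCAAAGTGGACTATGCACA
TTTACCCGGCATCAACCCAACATAAAACGGCGTTAAGTGCGTCGTAGTGAAGGGTCGGGACTCATGGGCC
GTCGCTCATCTAACTTAACCAAGGTCGATCTATAACGCCCGTGACTTCTGGGAATGTACGAATATAGAGT
CCGTCCTTGATGCTACCAGTCCTAAGTTCTATTCTGTACCCGAGCCCCTTGGTGGGCTGACCTAAAACTA
TACGTCCCTTTACCTCGGGCCGGATGCAGTCAGTTTGTAATGCAAACCTTGGTCCATTGAGAACCGGTAG
TTTCTTCTGCGCAGGGTTGAGGTCTTATTACAGATCGTGCTGTTACCGTTGTGTTCGTCGCCATATTACG
CAAAGGGACACATCACCAGGGCAAGTTCAAGCGCGCAAATCGAAGCTAAAGGGTATTGACCATTAACTGC
TATCCCTACTTACTGGCCTACACACAGGTGGGCTTTAAGCTCGTGCAAATCTCGCATCCTAGCCGACGTC
GCGCGTTCTGTCCAGGTAGGGCATTCATTAGCTGTAGCTCCAGCCACAAACTCGTGCGCGCGACGTCTTT
TCGCTCTATCGAGAGGTTGAGGGGGCTAGGTGTAGAGGACACCGCGCGCCCGTGTCGCCCGGACTGATTA
GCTCCTTTGCCACCTAGGACTCGAGCCTATCGATGCCAGCTCTTAGAGACTTCCGCCAACCGGCATACGG
ACCTAAGCCGGAATGTCCAGGGGGTGCCCTTTGATTGTGCTCTCGGACCATAATACTGACTCCGTCTATA
ACGTTTTGACAGCCAGAGCCTGATGATCAATCGTACGCGCTCAACGAACTGTATCGCCTCAGATTCTGTC
TTAGAACGTGTGCGTTATGCGGGCTAATCATAAACGGTAAGGCAACGTCTAGTAGTTATCAAGCACTTCC
CATCTATTGTTTCAGTTCACCAATCGCAGGGTATTCCAAGTGGTTGGAGGGGGAGGAGGCGACTGTAGGG
CTCTAAGCATCAGGGTTAGAATACTCTGACTAGCAGTGAGTTTATTCTACGACGCCGACTAACTGAAAGT
ATGCGTGCGAGTGTATGAAGCTCCTCCGTAGGTTCCCGTACTTTTAGCTCCCTGCTCGTGGGAGTCGGGC
TAGATAGGTATAAACGCACGTGTAATAGTAGAGACCCAGCCTAAGTCGGGGAGGGAGCCTAGCCCCGTCT
TGAAAGACTCCGGTAGTGTAAAGCGAGCTCTTTTCAAGAGATGGCAAGAGGCTCTATTCTTGCCTCTGTA
CAAAACCCTATAATCGTAATTGCCCAGGTTTACGGATACTCCCACCAGAATATGGAGCCTGACTCCAGTA
TCCTAATCTGTTGCCTTGTTCAAAAACTACGAAGTCTGTGACATAAGACAGAAAGGACTGGTAGGTGCCT
TAGTGCATTGTTAGATGTTCTCGGGACCATGCAGGCACTAACCAAATGCCATCATTCTGGACGAGCATGT
GCCGGATGCGGAGAGTTACTTAGACATAAATTTAACAAGTCGCATCGATGGAACGCTGTCGAAATGCGGT
CCGGGATCGAGAGGCGATCGGTTCGACCGAGGGAGTCTGAAAAGCTAACCGTCTGGCGATATAATAGCCT
CTGAGGCTGCGCCACCGCTATGCTATTCTAAGAGCTCTGAACGTGGCCTTAGCGCCAGTCACACAAAGGA
GGATGCTGAGTTGTAACGAGCAGATGCAATCCAGCTGATGCGCATCAGAATCGCTCGATTTACACAGTGT
ATGTTCTTCGCATGGAGACACGCTATGCCGCCACTATGCGGTGAGACCACCATGGCCACACGTCACCGGT
AATCCGGCGCCGGCTCAGGAACCAACCACACCCCTCCTTCAGTGACAATTCGGCCGGGTCGTACATAGTT
AGAATGAAAACACCGCGAAGAGTTATTGGTCAAAGGCGCATAAGCTTGTTGCGGCGGATAGGTCTAGTAG
CTTTTCACCCGAGCGCCCTCCGTGCTCCTATCATGGTTCAATGTCAACAGCACGTGTCGAGGATTCGTAC
CTACTACGGTCGACAGGCCACTATTAGACATCGCATTGATGATAGATCTTGTACTCGTGCCTAACCCGGA
AACTATAATTGCAACGGGCTACGTTGTGTTGAGTTCGTCATATTTAAAGGAGAATTAGCCGCGGAGAGGT
AATACTAAACGGATTCTCGGTAGGCATTTCAACCTTGGAACGAATCATAAAAATACCCTACAGCTGGATC
CAAAAATGCCGAATGCCTTAACTTTCCGGCTGAGACCCTTGCCACCTAGGCCTCGTAGTCGCGAACCCAT
CAACGCGCCGGTGTGAGACAAACACAGGTCATGGCTCACCGAGAGACAGTAAAACGAATCAATCGCTGAG
CAAACCGGGCAAGGTGTTAGCCGGTAACAACCGTACTATGTTACGTTCGTCGCGGATTAGGTGTACTACT
TCAACTGGGGTAGTTGTATGTGTTCACTCCCGCACACCATGCTAAGCGCATATCGTCAAAGATACTCACA
AAGGAGCAAACTGAACGTCCTGTTAAACGCTCCTTCGCATGCCCCGATCTCTTCGTCTTCGAGAGATGGT
TCTTTTATGCGCGTTAGCACTATCGCCTGATTGGCACGTGCCATGACCTTCGTCTCTTTGTCGCGGAATA
ATCGATTTGGCTCGACCCTGAGTATTATTGCTCGGCAAAACCTAGGGTACGCAGCGTAGCAGGATAAGGG
TCTGAATGGCGAGCTATACTTCCGGCCTTAGCTTTTATCTGACTACAGAGAATGATGAAAGAGAGATCAT
ACCTTCCCGCTGACCCACCCACCGAAGCCTGCGGTTATCCTCAGTTACGATCAGCTAATTAATGCATATA
GAGGGTGGCCTGCCATTTTGCACGAATCTCCAAATGTGCTTTTATTTTTGATTCTGCCTTAGTCAATCCG
CTGAAGGCCGTGGCACTACAAACCCTTACCCGACCACATCTCCCGTTTCATCCGATGCCAAGGAACTTAT
AGGAAAGGGCATGTGTGCCATCTAACATTCCAAGATCGCAGTCGATGTGGCAGACCTTAGCGTACGCTTT
ACTGGTTTGAACGTGGGGATCCTCTGGTGTCACTCGGTGGTCCATCAACTAGTTCAATTGGATTCGAGGT
AAGATATTTGTAAGAACAGCGAATAGGGTGAACAATCGACTGTTAAACCCGAAGTGCCTCAGATCATGGA
ATTCGATATGAACACTGCAGCAAGTTGAATACCGTCCGAAGCTCCTAGGATCGAGCCGGCTCTCTCGAGT
CCACTGGATCTACACTAGGGCATTAATCACCAAAATTACTTATCAAAAATCTTAACGGCCCCTGATATCA
TGCTGTCGCTGTCTTCGTGTTCTACCGTTTGCGGCGTGATGAGCTACTCCACCCAAGTAATGTTTTCCCT
AAAAGCTTGTAGGCACGGGGGCTCCTTAAAACGGGTCGTGAGCCCGATACTGTATAAGTCCCTACCCACG
CCGGATTTTTAACCTGGCCGCGTAGGTCGTCGCAGGTTATCTTAACACAGAATCCAATGTTGTGCGGTCG
GGACAACGGCATCCAAACTAGCCTCTGCTTATTCCAGCTGTTTAGCATATGTAGATTGCCCGTCTGTATA
TGTCGGAAGGATATTGGTGCTGCTCATATTGGGTCTATCTAACAATTTAGACGGAGTGGCACCCGTCAAT
TCGGTAAATACCATCCTTATTATAGGCAAATTCTAGCGACGCTTAGTAACAAAGACATGCAAGCTACTCG
TAGATCGAAAGTCCCTCTGTACGCCACGGACATAGTGTAGATTGGCGTCTTCCGGTCTCAGACCAGAAAC
GGCACCTGATTCCGGTTGCTGAGAATATCAGCAGTGCATCTTACTGACACAGTGAATAGTTCATATCGG
>SVA
TAAACTAATAGCCTTATTTAAACATTCCAACTTACCCTAACCCGGCACCAGCGGCGCCGAGGGTCCGTGT
GTGAGAATCGCGTCCAGTACACAGCAGTTCACTTACACTCATGGGCCGGCGTGCTAATGGAGAGGACTGC
GGTCCAACGTGGTGAATTCCTTGTACGCCGAATTGCCCGTATATCGTATGCCTCATTAGTATCGAAGCCC
TTGACGGGACCATTTCGAGTATCCTAGAGGACTAGCCGGTACCTAAGCATAAAATAGGGGAGTTTGCCCC
ACTCATACCTCTTCACTAAAGTGATCTTGTTTCTCTGTCCAAAGACTTATGAGCCTTCTGCTTAATACCA
GCGGTCGGTTGGAATCGCTTAACAAGCCAAATTGTCTATCCGGATGAAGTTCAACTGCCACCCCGCGTAG
TACAACGCATATGTGCTTTTCAAATATGGGAAATGACCGGTGGGATTAGCATCTCCCGCAGCCACGGGCA
CCTTACGTATTTTATGTCTTTGGGATCGTGGTACACCGGCCGTGGTAGAGTCGGGTCAAGCCGGCTAATG
GAGCTGAAAACCTCTAAGAATGCGAAGACCAACTAGGATTTGCACGCTTATCGGCCTAGCAGTACGTGTG
AGAGGGTGGGCGAAGGGACGCAGGATTAAATACCAATTACGGGGCTTAGCACTAATTGGTCCGAGTTCAA
GATAAAGAAAAGACCTGCGTAACTCGGTCGTACTGAGAACTTGCTGAGAACCGCGATCGTCGATCAACAT
CGTGTTAGAACACCGGACGTCATTCAATCACATAGAAAGCTAAGGTCTCGTAGCCTTGATAAAACCGGGC
GGTCCGAAATCCGTACATTACTACTCCATTGCCTGGTTCCCCGAACAATAGACCGTTCACACAAGGGTGT
ATTCGGGTGTCCGCTACCCGCCCCGCAAGGTAAATACTCATAGCGTCGGGCCTGACTTGAGTACTGCGAG
GCACATCATTTTACCATTCATCCGATTCGATTCACCCCGCTTCGTGCGGGCACGTAAGATACCCGCAGCA
TGGCCGGAGTAGCCGGAAGAATCTTTCACGACTATGGGGAAGTTTTCAGAGGATTTTGACAAGTCAGCAA
CACGCATAATCACGTCCCCATAAGTCGCCAATCGGCCCTGGCGCATCCATAGTTTGGTGTCTGACACATG
ATGTCCAGCTGTTTCACAAAATCTATATCCTGAGAGCGCATCTGCGCCGTGTAGCTATATCAGAAGACCC
GAATGTCAATTCTGTTAGCTAAACTGCCATCGGTCTATTAGTCTTGCATTATCAAT
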