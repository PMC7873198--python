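gene,role,forward,reverse
ACTB,reference,ACCTTCTACAATGAGCTGCG,CTGGATGGCTACGTACATGG
MDM2,target,GCGTGGAATTTGAAGTTGAG,TCCTGTATCGCTTTCTCCTGTCTG
CDKN1A,target,CAGATCCACAGCGATATCCAG,AGAGACAACGGCACACTTTG
BBC3,target,CTGGAGGGTCATGTACAATCTC,GGTGTCAGAAGGCGGAG
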