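>pbuE_adenine_riboswitch_PLOR_template 155 nt dsDNA template, T7 promoter on reverse complement
CCGCGGATGCGGAAAAAAAATCCTGATTACAAAAAATGTCATAAACAAATTTTGTAATCA
GGATTTTACGGTTCCTGGTAGACACCCTCAAACCATATTATTGAGGTTATACAACTTCCC
TATAGTGAGTCGTATTATGGACTAGCTGAATCAGA
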