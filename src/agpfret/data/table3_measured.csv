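# Measured FRET efficiencies between multilabeled donor Agp2 and Agp1 labeled
# at single positions (mean +/- SE of four independent measurements), with the
# published relative-distance and apparent-distance columns as printed.
donor,acceptor,position,efficiency,se,significance,rel_distance_printed,apparent_r_printed
Agp2,S122C,122,0.09,0.02,ab,1.47,73
Agp2,A362C,362,0.10,0.02,,1.45,72
Agp2,K517C,517,0.15,0.04,,1.34,67
Agp2,R535C,535,0.21,0.02,a,1.24,62
Agp2,K554C,554,0.28,0.06,b,1.17,58
Agp2,R603C,603,0.20,0.03,,1.26,63
Agp2,A362C PCM,362,0.00,0.03,**,,
Agp2-PCM,K517C,517,0.14,0.03,,1.35,67
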