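substance,T_K,cp_J_per_gK
glycine,300,1.33
glycine,340,1.45
glycine,380,1.57
glycine,420,1.69
glycine,460,1.80
glycine,480,1.86
l-alanine,300,1.38
l-alanine,340,1.51
l-alanine,380,1.64
l-alanine,420,1.76
l-alanine,460,1.88
l-alanine,480,1.94
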