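api,logp_sle,method1,method2,method3,literature
naproxen,2.57,3.45,3.31,3.08,3.34
ibuprofen,4.42,2.73,2.84,2.95,2.48
lidocaine,2.09,0.30,1.70,1.96,2.45
griseofulvin,2.26,,1.34,1.34,1.98
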