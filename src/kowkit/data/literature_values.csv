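substance,ionizable,property_stated,property_reported,determination,ph,value,conc_mmol_L,ionic_strength_mmol_L,reliable,reference_id
carbamazepine,False,logP,logP,exp,7,1.40,,0.1,True,ref34
carbamazepine,False,logP,logP,exp,,1.90,,,True,ref34
carbamazepine,False,logKow,logKow,calc,,2.45,0,0,False,ref35
felodipine,False,logP,logP,exp,,3.86,,,True,ref36
felodipine,False,logP,unknown,unknown,,5.58,,,False,ref37
fenofibrate,False,logP,unknown,unknown,,4.60,,,False,ref38
fenofibrate,False,logP,unknown,unknown,,5.20,,,False,ref39
fenofibrate,False,logP,unknown,unknown,,5.80,,,False,ref40
griseofulvin,False,logP,logP,exp,7.4,1.98,1.6,0.15,True,ref41
griseofulvin,False,logP,unknown,unknown,,2.15,,,False,ref42
griseofulvin,False,logP,unknown,unknown,,2.36,,,False,ref43
cinnarizine,True,logP,unknown,unknown,,5.60,,,False,ref44
cinnarizine,True,logP,unknown,unknown,,5.71,,,False,ref37
cinnarizine,True,logP,unknown,unknown,,5.80,,,False,ref45
itraconazole,True,logKow,unknown,unknown,,5.66,,,False,ref46
itraconazole,True,logP,unknown,unknown,,6.20,,,False,ref47
lidocaine,True,logDow,logD,exp,7.4,1.63,,0.15,False,ref48
lidocaine,True,logP,logP,exp&conv,,2.45,,0.15,True,ref11
lidocaine,True,logP,unknown,unknown,11.2,3.40,,0,False,ref49
ritonavir,True,logP,unknown,unknown,,0.45,,,False,ref50
ritonavir,True,logP,logDow,calc,,1.54,0,0,False,ref51
ritonavir,True,logP,unknown,unknown,6.8,4.30,,0.1,False,ref52
terfenadine,True,logP,logD,exp,,4.47,,0.15,False,ref34
terfenadine,True,logP,logP,exp,12,4.96,,0.1,True,ref34
terfenadine,True,logP,logD,exp,,6.08,,,False,ref34
thiabendazole,True,logKow,logD,exp,,1.94,1,0.75,False,ref53
thiabendazole,True,logKow,logKow,calc,,2.30,0,0,False,ref53
thiabendazole,True,logKow,unknown,unknown,6,2.47,,,False,ref53
thiabendazole,True,logP,logD,exp,,2.55,0.01,0,True,ref54
artemisinin,True,logP,logDow,calc,,1.72,0,,False,ref55
artemisinin,True,logP,unknown,unknown,,2.94,,,False,ref56
celecoxib,True,logP,unknown,unknown,,3.50,,0.16,False,ref57
celecoxib,True,logP,logDow,calc,,3.68,0,0,False,ref58
celecoxib,True,logP,logP,exp,2,3.90,,0.1,False,ref34
celecoxib,True,logD,logD,exp,7.4,4.30,0.02,0.1,True,ref59
glibenclamide,True,logP,unknown,unknown,,0.30,,,False,ref60
glibenclamide,True,logP,unknown,unknown,,3.08,,,False,ref37
glibenclamide,True,logP,unknown,unknown,,4.80,,,False,ref61
ibuprofen,True,logDow,logD,exp,7.4,1.00,6.4,0,True,ref62
ibuprofen,True,logKow,logP,exp&conv,,2.48,2.4,0,True,ref63
ibuprofen,True,logP,logP,exp&conv,,3.97,,0.15,False,ref11
indomethacin,True,logP,unknown,unknown,,3.51,,,False,ref37
indomethacin,True,logP,logP,exp,2,3.89,,0.15,False,ref34
indomethacin,True,logP,unknown,unknown,,4.27,,,False,ref64
naproxen,True,logD,logD,unknown,7.4,0.33,,0.15,True,ref65
naproxen,True,logP,unknown,unknown,5,2.38,,0,False,ref66
naproxen,True,logKow,unknown,unknown,,3.18,,,False,ref67
naproxen,True,logP,logP,unknown,2,3.34,,,True,ref65
nifedipine,True,logP,logD,exp,,0.30,3.4-12.8,0,True,ref68
nifedipine,True,logKow,logD,exp,7.4,2.36,,0,False,ref69
nifedipine,True,logKow,logDow,calc,,3.17,0,0,False,ref35
paracetamol,True,logKow,unknown,unknown,,0.48,,,False,ref70
paracetamol,True,logDow,logD,exp,7.4,0.78,12.7,0,True,ref62
paracetamol,True,logKow,unknown,unknown,,3.02,5,,False,ref71
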