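((Beella_digitata_KF769946:0.1,(((((((Globigerinella_siphonifera_IIIa_KF769861:0.1,(Globigerinella_siphonifera_Ia_Z83959:0.1,Globigerinella_siphonifera_Ib_JQ743484:0.1):0.05):0.05,Globigerinella_siphonifera_IIb_KF769820:0.1):0.05,Globigerinella_siphonifera_IIa2_KF769629:0.1):0.05,Globigerinella_siphonifera_IIa3_KF769634:0.1):0.05,Globigerinella_siphonifera_IIa5_KF769785:0.1):0.05,Globigerinella_siphonifera_IIa3_Z83960:0.1):0.05,Globigerinella_siphonifera_IIa1_U80788:0.1):0.05):0.05,((Candeina_nitida_AB263435:0.1,(Globigerinita_glutinata_AB263433:0.1,Globigerinita_uvula_FJ643302:0.1):0.05):0.05,((((Globigerina_bulloides_IIa_GU060422:0.1,(Globigerina_bulloides_IIe_GQ293071:0.1,(Globigerina_bulloides_IIf_GQ293069:0.1,(((Globigerina_bulloides_Ia_GQ293068:0.1,Globigerina_bulloides_Ic_GQ293072:0.1):0.05,Globigerina_bulloides_Ie_GU060421:0.1):0.05,Globigerina_bulloides_Id_GQ293070:0.1):0.05):0.05):0.05):0.05,Globigerina_bulloides_IIb_AF250109:0.1):0.05,Globigerina_bulloides_IId_AY241713:0.1):0.05,Globigerina_falconensis_FJ643416:0.1):0.05):0.05,(((Globigerinoides_conglobatus_Z83967:0.1,((Globigerinoides_elongatus_IIa0_EU012463:0.1,Globigerinoides_elongatus_IIa2_EU012452:0.1):0.05,(Globigerinoides_ruber_pink_Z83966:0.1,(Globigerinoides_ruber_white_Ia_EU012458:0.1,Globigerinoides_ruber_white_Ib2_EU012459:0.1):0.05):0.05):0.05):0.05,Globoturborotalita_rubescens_JQ799894:0.1):0.05,(Globigerinoides_sacculifer_AB263459:0.1,(Orbulina_universa_AF102229:0.1,Sphaeroidinella_dehiscens_KM386666:0.1):0.05):0.05):0.05);
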