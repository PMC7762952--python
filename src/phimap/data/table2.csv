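complex_id,ncbd_variant,cid_variant,probe,condition,kon,kon_se,koff,koff_se,koff_source,status,group
cambrian_pWT_ML,pWT,ML,T2073W,,30.4,2.5,24.7,0.3,displacement,ok,reference
cambrian_pWT_A1047G,pWT,A1047G,T2073W,,24.8,2.5,53.8,0.8,binding_fit,ok,Ca1_helix
cambrian_pWT_D1050A,pWT,D1050A,T2073W,,31.7,3.2,21.3,0.2,displacement,ok,Ca1_helix
cambrian_pWT_D1050G,pWT,D1050G,T2073W,,18.7,1.9,72,0.9,binding_fit,ok,Ca1_helix
cambrian_pWT_S1054A,pWT,S1054A,T2073W,,39.0,3.9,14.9,0.1,displacement,ok,Ca1_helix
cambrian_pWT_S1054G,pWT,S1054G,T2073W,,23.2,2.3,74,1,binding_fit,ok,Ca1_helix
cambrian_pWT_M1062A,pWT,M1062A,T2073W,,29.8,3.0,16.1,0.3,displacement,ok,Ca2_helix
cambrian_pWT_M1062G,pWT,M1062G,T2073W,,26.3,2.6,21.2,0.2,displacement,ok,Ca2_helix
cambrian_pWT_A1065G,pWT,A1065G,T2073W,,28.5,2.9,77,1,binding_fit,ok,Ca2_helix
cambrian_pWT_R1069A,pWT,R1069A,T2073W,,26.0,0.26,66.7,0.6,binding_fit,ok,Ca2_helix
cambrian_pWT_R1069G,pWT,R1069G,T2073W,,23.0,2.3,209,4,binding_fit,ok,Ca2_helix
cambrian_pWT_L1048A,pWT,L1048A,T2073W,,13.5,1.4,105,1,binding_fit,ok,interface
cambrian_pWT_L1049A,pWT,L1049A,T2073W,,18.7,1.9,71.8,0.6,binding_fit,ok,interface
cambrian_pWT_D1053A,pWT,D1053A,T2073W,,46.4,4.6,22.3,0.2,displacement,ok,electrostatic
cambrian_pWT_L1055A,pWT,L1055A,T2073W,,14.0,1.4,29.0,0.4,displacement,ok,interface
cambrian_pWT_L1056A,pWT,L1056A,T2073W,,,,,,,too_unstable,interface
cambrian_pWT_L1064A,pWT,L1064A,T2073W,,,,,,,too_unstable,interface
cambrian_pWT_I1067V,pWT,I1067V,T2073W,,20.4,2,93,1,binding_fit,ok,interface
cambrian_pWT_I1067A,pWT,I1067A,T2073W,,,,,,,too_unstable,interface
cambrian_pWT_D1068A,pWT,D1068A,T2073W,,39.6,4,59.5,0.7,binding_fit,ok,electrostatic
cambrian_pWT_L1071A,pWT,L1071A,T2073W,,,,,,,too_unstable,interface
cambrian_L2067A_ML,L2067A,ML,T2073W,,14.8,1.5,67,1,binding_fit,ok,interface
cambrian_L2071A_ML,L2071A,ML,T2073W,,22.1,2.2,17.4,0.1,displacement,ok,interface
cambrian_L2074A_ML,L2074A,ML,T2073W,,,,,,,too_unstable,interface
cambrian_K2075M_ML,K2075M,ML,T2073W,,14.5,1.5,26.3,0.4,displacement,ok,electrostatic
cambrian_K2075M_D1053A,K2075M,D1053A,T2073W,,18.0,1.8,26.2,0.2,binding_fit,ok,electrostatic
cambrian_L2086A_ML,L2086A,ML,T2073W,,,,,,,too_unstable,interface
cambrian_L2087A_ML,L2087A,ML,T2073W,,15.1,1.5,26.4,0.5,displacement,ok,interface
cambrian_L2090A_ML,L2090A,ML,T2073W,,,,,,,too_unstable,interface
cambrian_L2096A_ML,L2096A,ML,T2073W,,14.9,1.5,40.7,0.5,binding_fit,ok,interface
cambrian_A2099G_ML,A2099G,ML,T2073W,,27.6,2.8,122,1,binding_fit,ok,interface
cambrian_I2101V_ML,I2101V,ML,T2073W,,29.3,0.1,23.8,0.3,displacement,ok,interface
cambrian_I2101A_ML,I2101A,ML,T2073W,,,,,,,too_unstable,interface
cambrian_R2104M_ML,R2104M,ML,T2073W,,,,,,,too_unstable,electrostatic
cambrian_R2104M_D1053A,R2104M,D1053A,T2073W,,,,,,,too_unstable,electrostatic
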