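complex_id,ncbd_variant,cid_variant,probe,condition,kon,kon_se,koff,koff_se,koff_source,status,group
altprobe_L2067W_ML,pWT,ML,L2067W,,17.9,1.8,39.2,0.2,binding_fit,ok,reference
altprobe_L2067W_A1047G,pWT,A1047G,L2067W,,12.9,1.3,64.7,0.6,binding_fit,ok,Ca1_helix
altprobe_L2067W_L1049A,pWT,L1049A,L2067W,,9.6,0.96,52.9,0.2,binding_fit,ok,interface
altprobe_L2067W_D1053A,pWT,D1053A,L2067W,,29.3,2.9,25.7,0.1,binding_fit,ok,electrostatic
altprobe_L2067W_I1067V,pWT,I1067V,L2067W,,10.7,1.1,132,1,binding_fit,ok,interface
altprobe_L2067W_A1065G,pWT,A1065G,L2067W,,14.4,1.4,125,1,binding_fit,ok,Ca2_helix
altprobe_L2067W_D1068A,pWT,D1068A,L2067W,,27.0,2.7,178,2,binding_fit,ok,electrostatic
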