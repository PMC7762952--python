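complex_id,ncbd_variant,cid_variant,probe,condition,kon,kon_se,koff,koff_se,koff_source,status,group
human_pWT_WT,pWT,WT,Y2108W,,25.0,2.5,2.66,0.01,displacement,ok,reference
human_pWT_E1065A,pWT,E1065A,Y2108W,,24.9,2.5,2.59,0.01,displacement,ok,Ca2_helix
human_pWT_E1065G,pWT,E1065G,Y2108W,,23.7,2.4,7.8,0.1,displacement,ok,Ca2_helix
human_pWT_R1069A,pWT,R1069A,Y2108W,,27.7,2.8,8.8,0.1,displacement,ok,Ca2_helix
human_pWT_R1069G,pWT,R1069G,Y2108W,,26.4,2.6,76,2,binding_fit,ok,Ca2_helix
human_pWT_E1075A,pWT,E1075A,Y2108W,,26.5,2.7,3.12,0.06,displacement,ok,Ca3_helix
human_pWT_E1075G,pWT,E1075G,Y2108W,,23.7,2.4,3.44,0.02,displacement,ok,Ca3_helix
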