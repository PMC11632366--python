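region_id,hemisphere,bilateral_pair_id,braak_stage,reference_candidate,composites
bankssts_L,left,bankssts,5,false,braak5;temporoparietal
bankssts_R,right,bankssts,5,false,braak5;temporoparietal
caudal_anterior_cingulate_L,left,caudal_anterior_cingulate,4,false,braak4;rest
caudal_anterior_cingulate_R,right,caudal_anterior_cingulate,4,false,braak4;rest
caudal_middle_frontal_L,left,caudal_middle_frontal,5,false,braak5;rest
caudal_middle_frontal_R,right,caudal_middle_frontal,5,false,braak5;rest
cuneus_L,left,cuneus,6,false,braak6;rest
cuneus_R,right,cuneus,6,false,braak6;rest
entorhinal_L,left,entorhinal,1,false,braak1;mesial_temporal;meta_temporal
entorhinal_R,right,entorhinal,1,false,braak1;mesial_temporal;meta_temporal
frontal_pole_L,left,frontal_pole,5,false,braak5;rest
frontal_pole_R,right,frontal_pole,5,false,braak5;rest
fusiform_L,left,fusiform,3,false,braak3;mesial_temporal;meta_temporal
fusiform_R,right,fusiform,3,false,braak3;mesial_temporal;meta_temporal
inferior_parietal_L,left,inferior_parietal,5,false,braak5;temporoparietal
inferior_parietal_R,right,inferior_parietal,5,false,braak5;temporoparietal
inferior_temporal_L,left,inferior_temporal,4,false,braak4;meta_temporal;temporoparietal
inferior_temporal_R,right,inferior_temporal,4,false,braak4;meta_temporal;temporoparietal
insula_L,left,insula,4,false,braak4;rest
insula_R,right,insula,4,false,braak4;rest
isthmus_cingulate_L,left,isthmus_cingulate,4,false,braak4;temporoparietal
isthmus_cingulate_R,right,isthmus_cingulate,4,false,braak4;temporoparietal
lateral_occipital_L,left,lateral_occipital,5,false,braak5;rest
lateral_occipital_R,right,lateral_occipital,5,false,braak5;rest
lateral_orbitofrontal_L,left,lateral_orbitofrontal,5,false,braak5;rest
lateral_orbitofrontal_R,right,lateral_orbitofrontal,5,false,braak5;rest
lingual_L,left,lingual,3,false,braak3;rest
lingual_R,right,lingual,3,false,braak3;rest
medial_orbitofrontal_L,left,medial_orbitofrontal,5,false,braak5;rest
medial_orbitofrontal_R,right,medial_orbitofrontal,5,false,braak5;rest
middle_temporal_L,left,middle_temporal,4,false,braak4;meta_temporal;temporoparietal
middle_temporal_R,right,middle_temporal,4,false,braak4;meta_temporal;temporoparietal
paracentral_L,left,paracentral,6,false,braak6;rest
paracentral_R,right,paracentral,6,false,braak6;rest
parahippocampal_L,left,parahippocampal,3,false,braak3;mesial_temporal;meta_temporal
parahippocampal_R,right,parahippocampal,3,false,braak3;mesial_temporal;meta_temporal
pars_opercularis_L,left,pars_opercularis,5,false,braak5;rest
pars_opercularis_R,right,pars_opercularis,5,false,braak5;rest
pars_orbitalis_L,left,pars_orbitalis,5,false,braak5;rest
pars_orbitalis_R,right,pars_orbitalis,5,false,braak5;rest
pars_triangularis_L,left,pars_triangularis,5,false,braak5;rest
pars_triangularis_R,right,pars_triangularis,5,false,braak5;rest
pericalcarine_L,left,pericalcarine,6,false,braak6;rest
pericalcarine_R,right,pericalcarine,6,false,braak6;rest
postcentral_L,left,postcentral,6,false,braak6;rest
postcentral_R,right,postcentral,6,false,braak6;rest
posterior_cingulate_L,left,posterior_cingulate,4,false,braak4;temporoparietal
posterior_cingulate_R,right,posterior_cingulate,4,false,braak4;temporoparietal
precentral_L,left,precentral,6,false,braak6;rest
precentral_R,right,precentral,6,false,braak6;rest
precuneus_L,left,precuneus,5,false,braak5;temporoparietal
precuneus_R,right,precuneus,5,false,braak5;temporoparietal
rostral_anterior_cingulate_L,left,rostral_anterior_cingulate,4,false,braak4;rest
rostral_anterior_cingulate_R,right,rostral_anterior_cingulate,4,false,braak4;rest
rostral_middle_frontal_L,left,rostral_middle_frontal,5,false,braak5;rest
rostral_middle_frontal_R,right,rostral_middle_frontal,5,false,braak5;rest
superior_frontal_L,left,superior_frontal,5,false,braak5;rest
superior_frontal_R,right,superior_frontal,5,false,braak5;rest
superior_parietal_L,left,superior_parietal,5,false,braak5;temporoparietal
superior_parietal_R,right,superior_parietal,5,false,braak5;temporoparietal
superior_temporal_L,left,superior_temporal,5,false,braak5;temporoparietal
superior_temporal_R,right,superior_temporal,5,false,braak5;temporoparietal
supramarginal_L,left,supramarginal,5,false,braak5;temporoparietal
supramarginal_R,right,supramarginal,5,false,braak5;temporoparietal
temporal_pole_L,left,temporal_pole,4,false,braak4;rest
temporal_pole_R,right,temporal_pole,4,false,braak4;rest
transverse_temporal_L,left,transverse_temporal,5,false,braak5;temporoparietal
transverse_temporal_R,right,transverse_temporal,5,false,braak5;temporoparietal
amygdala_L,left,amygdala,3,false,braak3;mesial_temporal;meta_temporal
amygdala_R,right,amygdala,3,false,braak3;mesial_temporal;meta_temporal
hippocampus_L,left,hippocampus,2,false,braak2
hippocampus_R,right,hippocampus,2,false,braak2
ventral_dc_L,left,ventral_dc,none,false,
ventral_dc_R,right,ventral_dc,none,false,
cerebellum_cortex_L,left,cerebellum_cortex,none,true,cerebellum_cortex;composite_reference;whole_cerebellum
cerebellum_wm_L,left,cerebellum_wm,none,true,composite_reference;whole_cerebellum
inferior_cerebellum_gm_L,left,inferior_cerebellum_gm,none,true,inferior_cerebellum_gm
cerebellum_cortex_R,right,cerebellum_cortex,none,true,cerebellum_cortex;composite_reference;whole_cerebellum
cerebellum_wm_R,right,cerebellum_wm,none,true,composite_reference;whole_cerebellum
inferior_cerebellum_gm_R,right,inferior_cerebellum_gm,none,true,inferior_cerebellum_gm
brainstem,midline,none,none,true,brainstem;composite_reference
eroded_subcortical_wm,midline,none,none,true,composite_reference;eroded_subcortical_wm
cc_anterior,midline,none,none,false,
cc_mid_anterior,midline,none,none,false,
cc_central,midline,none,none,false,
cc_mid_posterior,midline,none,none,false,
cc_posterior,midline,none,none,false,
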