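organ,w_t,sex,remainder
red_bone_marrow,0.12,both,0
colon,0.12,both,0
lung,0.12,both,0
stomach,0.12,both,0
breast,0.12,female,0
gonads,0.08,both,0
bladder,0.04,both,0
liver,0.04,both,0
esophagus,0.04,both,0
thyroid,0.04,both,0
skin,0.01,both,0
bone_surface,0.01,both,0
salivary_glands,0.01,both,0
brain,0.01,both,0
spleen,0.0092,both,1
kidney,0.0092,both,1
heart,0.0092,both,1
pancreas,0.0092,both,1
oral_mucosa,0.0092,both,1
lymph_nodes,0.0092,both,1
muscle,0.0092,both,1
small_intestine,0.0092,both,1
gall_bladder,0.0092,both,1
adrenal_gland,0.0092,both,1
prostate,0.0092,male,1
uterus,0.0092,female,1
et_region,0.0092,both,1
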