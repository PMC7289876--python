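organ,equivalent_mGy,equivalent_sd,w_t,ed_female_mSv,ed_female_sd,ed_male_mSv,ed_male_sd,c_female,c_male,lar_per_100k,lar_sd
red_bone_marrow,12.3,2.3,0.12,1.49,0.24,1.47,0.28,0.125,0.126,,
colon,11.2,2.8,0.12,1.28,0.08,1.36,0.38,0.108,0.116,4.69,1.88
lung,13.4,1.9,0.12,1.48,0.15,1.64,0.38,0.125,0.14,13.25,4.24
stomach,12.2,1.5,0.12,1.39,0.06,1.48,0.23,0.117,0.127,1.43,0.47
breast,10.9,0.8,0.12,1.30,0.09,,,0.11,,2.46,1.62
gonads,14.6,4.1,0.08,0.74,0.07,1.29,0.26,0.063,0.111,1.94,0.84
bladder,11.7,2.0,0.04,0.40,0.05,0.49,0.06,0.034,0.042,1.88,0.47
liver,12.0,1.2,0.04,0.46,0.04,0.49,0.08,0.039,0.042,1.22,0.41
esophagus,11.1,1.4,0.04,0.42,0.05,0.45,0.01,0.035,0.039,,
thyroid,21.2,3.2,0.04,0.90,0.04,0.83,0.05,0.076,0.071,,
skin,11.0,2.1,0.01,0.09,0.00,0.11,0.03,0.08,0.01,,
bone_surface,26.6,4.7,0.01,0.24,0.01,0.27,0.03,0.02,0.023,,
salivary_glands,14.3,2.8,0.01,0.12,0.01,0.15,0.03,0.01,0.013,,
brain,12.7,3.3,0.01,0.10,0.00,0.14,0.03,0.08,0.012,,
spleen,12.4,1.7,0.0092,0.11,0.01,0.12,0.02,0.009,0.01,,
kidney,17.0,2.1,0.0092,0.16,0.01,0.15,0.02,0.014,0.013,,
heart,12.5,1.5,0.0092,0.12,0.01,0.12,0.01,0.01,0.01,,
pancreas,11.7,1.2,0.0092,0.11,0.01,0.11,0.01,0.009,0.009,,
oral_mucosa,13.5,3.1,0.0092,0.12,0.01,0.13,0.03,0.009,0.011,,
lymph_nodes,12.6,2.2,0.0092,0.12,0.02,0.12,0.02,0.009,0.01,,
muscle,11.5,1.9,0.0092,0.11,0.01,0.11,0.02,0.008,0.009,,
small_intestine,13.2,1.9,0.0092,0.12,0.00,0.13,0.02,0.009,0.011,,
gall_bladder,11.6,1.3,0.0092,0.11,0.01,0.11,0.01,0.008,0.009,,
adrenal_gland,10.2,1.3,0.0092,0.09,0.01,0.10,0.01,0.008,0.008,,
prostate,11.4,3.2,0.0092,,,0.10,0.03,,0.008,0.74,0.25
uterus,9.9,1.1,0.0092,0.09,0.01,,,0.008,,0.28,0.09
et_region,8.7,7.1,0.0092,0.08,0.06,0.07,0.07,0.009,0.006,,
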