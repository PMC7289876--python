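sex,age_anchor,site,n_per_100k_at_100mGy,source_label
male,20,all_solid,511,BEIR-VII-12D-2
male,30,all_solid,416,BEIR-VII-12D-2
male,40,all_solid,377,BEIR-VII-12D-2
male,50,all_solid,360,BEIR-VII-12D-2
male,60,all_solid,319,BEIR-VII-12D-2
male,70,all_solid,250,BEIR-VII-12D-2
male,80,all_solid,153,BEIR-VII-12D-2
female,20,all_solid,762,BEIR-VII-12D-2
female,30,all_solid,620,BEIR-VII-12D-2
female,40,all_solid,545,BEIR-VII-12D-2
female,50,all_solid,505,BEIR-VII-12D-2
female,60,all_solid,431,BEIR-VII-12D-2
female,70,all_solid,327,BEIR-VII-12D-2
female,80,all_solid,181,BEIR-VII-12D-2
male,20,leukemia,67,BEIR-VII-12D-2
male,30,leukemia,64,BEIR-VII-12D-2
male,40,leukemia,67,BEIR-VII-12D-2
male,50,leukemia,71,BEIR-VII-12D-2
male,60,leukemia,73,BEIR-VII-12D-2
male,70,leukemia,69,BEIR-VII-12D-2
male,80,leukemia,51,BEIR-VII-12D-2
female,20,leukemia,49,BEIR-VII-12D-2
female,30,leukemia,47,BEIR-VII-12D-2
female,40,leukemia,52,BEIR-VII-12D-2
female,50,leukemia,54,BEIR-VII-12D-2
female,60,leukemia,58,BEIR-VII-12D-2
female,70,leukemia,57,BEIR-VII-12D-2
female,80,leukemia,38,BEIR-VII-12D-2
male,20,stomach,21,BEIR-VII-12D-2
male,30,stomach,16,BEIR-VII-12D-2
male,40,stomach,15,BEIR-VII-12D-2
male,50,stomach,13,BEIR-VII-12D-2
male,60,stomach,11,BEIR-VII-12D-2
male,70,stomach,8,BEIR-VII-12D-2
male,80,stomach,4,BEIR-VII-12D-2
female,20,stomach,29,BEIR-VII-12D-2
female,30,stomach,21,BEIR-VII-12D-2
female,40,stomach,20,BEIR-VII-12D-2
female,50,stomach,19,BEIR-VII-12D-2
female,60,stomach,16,BEIR-VII-12D-2
female,70,stomach,13,BEIR-VII-12D-2
female,80,stomach,8,BEIR-VII-12D-2
male,20,colon,84,BEIR-VII-12D-2
male,30,colon,61,BEIR-VII-12D-2
male,40,colon,60,BEIR-VII-12D-2
male,50,colon,57,BEIR-VII-12D-2
male,60,colon,50,BEIR-VII-12D-2
male,70,colon,38,BEIR-VII-12D-2
male,80,colon,24,BEIR-VII-12D-2
female,20,colon,53,BEIR-VII-12D-2
female,30,colon,38,BEIR-VII-12D-2
female,40,colon,37,BEIR-VII-12D-2
female,50,colon,35,BEIR-VII-12D-2
female,60,colon,31,BEIR-VII-12D-2
female,70,colon,25,BEIR-VII-12D-2
female,80,colon,15,BEIR-VII-12D-2
male,20,liver,23,BEIR-VII-12D-2
male,30,liver,16,BEIR-VII-12D-2
male,40,liver,16,BEIR-VII-12D-2
male,50,liver,14,BEIR-VII-12D-2
male,60,liver,12,BEIR-VII-12D-2
male,70,liver,8,BEIR-VII-12D-2
male,80,liver,4,BEIR-VII-12D-2
female,20,liver,12,BEIR-VII-12D-2
female,30,liver,9,BEIR-VII-12D-2
female,40,liver,8,BEIR-VII-12D-2
female,50,liver,8,BEIR-VII-12D-2
female,60,liver,7,BEIR-VII-12D-2
female,70,liver,5,BEIR-VII-12D-2
female,80,liver,3,BEIR-VII-12D-2
male,20,lung,155,BEIR-VII-12D-2
male,30,lung,104,BEIR-VII-12D-2
male,40,lung,101,BEIR-VII-12D-2
male,50,lung,97,BEIR-VII-12D-2
male,60,lung,86,BEIR-VII-12D-2
male,70,lung,65,BEIR-VII-12D-2
male,80,lung,38,BEIR-VII-12D-2
female,20,lung,313,BEIR-VII-12D-2
female,30,lung,212,BEIR-VII-12D-2
female,40,lung,204,BEIR-VII-12D-2
female,50,lung,196,BEIR-VII-12D-2
female,60,lung,172,BEIR-VII-12D-2
female,70,lung,129,BEIR-VII-12D-2
female,80,lung,74,BEIR-VII-12D-2
female,20,breast,101,BEIR-VII-12D-2
female,30,breast,61,BEIR-VII-12D-2
female,40,breast,35,BEIR-VII-12D-2
female,50,breast,19,BEIR-VII-12D-2
female,60,breast,9,BEIR-VII-12D-2
female,70,breast,5,BEIR-VII-12D-2
female,80,breast,2,BEIR-VII-12D-2
male,20,prostate,9,BEIR-VII-12D-2
male,30,prostate,7,BEIR-VII-12D-2
male,40,prostate,6,BEIR-VII-12D-2
male,50,prostate,7,BEIR-VII-12D-2
male,60,prostate,7,BEIR-VII-12D-2
male,70,prostate,7,BEIR-VII-12D-2
male,80,prostate,5,BEIR-VII-12D-2
female,20,uterus,6,BEIR-VII-12D-2
female,30,uterus,4,BEIR-VII-12D-2
female,40,uterus,4,BEIR-VII-12D-2
female,50,uterus,3,BEIR-VII-12D-2
female,60,uterus,3,BEIR-VII-12D-2
female,70,uterus,2,BEIR-VII-12D-2
female,80,uterus,1,BEIR-VII-12D-2
female,20,ovary,28,BEIR-VII-12D-2
female,30,ovary,20,BEIR-VII-12D-2
female,40,ovary,20,BEIR-VII-12D-2
female,50,ovary,18,BEIR-VII-12D-2
female,60,ovary,15,BEIR-VII-12D-2
female,70,ovary,11,BEIR-VII-12D-2
female,80,ovary,5,BEIR-VII-12D-2
male,20,bladder,23,BEIR-VII-12D-2
male,30,bladder,17,BEIR-VII-12D-2
male,40,bladder,17,BEIR-VII-12D-2
male,50,bladder,17,BEIR-VII-12D-2
male,60,bladder,17,BEIR-VII-12D-2
male,70,bladder,15,BEIR-VII-12D-2
male,80,bladder,10,BEIR-VII-12D-2
female,20,bladder,30,BEIR-VII-12D-2
female,30,bladder,22,BEIR-VII-12D-2
female,40,bladder,22,BEIR-VII-12D-2
female,50,bladder,22,BEIR-VII-12D-2
female,60,bladder,22,BEIR-VII-12D-2
female,70,bladder,19,BEIR-VII-12D-2
female,80,bladder,13,BEIR-VII-12D-2
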