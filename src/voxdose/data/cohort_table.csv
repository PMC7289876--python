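id,age_y,sex,weight_kg,bmi,dlp_mGycm,ctdi_vol_mGy,eff_mas,ed_dlp_mSv,ed_nci_mSv,ed_mc_mSv,dev_nci_pct,dev_mc_pct,k_mc,lar_per_100k,err_pct
P01,30,female,70,21.6,675,5.8,86,10.1,7.4,11.1,-26.7,9.9,0.016,60,0.34
P02,48,female,54,21.1,545,5.4,80,8.2,7.6,10.9,-7.3,32.9,0.020,52,0.30
P03,55,female,46,17.3,554,5.5,81,8.3,8.3,11.5,0.0,38.9,0.021,51,0.29
P04,56,female,62,21.5,634,6.3,93,9.5,8.7,12.3,-8.4,29.5,0.019,53,0.30
P05,79,female,65,24.5,656,6.5,96,9.8,8.6,12.7,-12.2,29.6,0.019,26,0.15
P06,30,male,51,16.8,464,4.6,68,7.0,7.1,8.5,1.4,21.4,0.018,33,0.15
P07,36,male,68,24.1,783,6.8,100,11.8,9.4,10.9,-20.3,-7.6,0.014,41,0.19
P08,44,male,80,25.0,841,7.3,107,12.6,9.2,11.9,-27.0,-5.6,0.014,44,0.20
P09,52,male,84,25.9,827,7.1,105,12.4,8.8,11.1,-29.0,-10.5,0.013,39,0.18
P10,53,male,77,24.3,841,7.3,107,12.6,9.6,10.9,-23.8,-13.5,0.013,38,0.17
P11,53,male,72,24.3,836,7.2,106,12.5,10.1,11.5,-19.2,-8.0,0.014,40,0.18
P12,54,male,67,20.7,630,6.4,92,9.5,9.0,10.3,-5.3,8.4,0.016,35,0.16
P13,57,male,125,37.3,1399,12.1,178,21.0,11.7,13.9,-44.3,-33.8,0.010,46,0.21
P14,58,male,84,25.9,875,7.6,111,13.1,9.3,8.3,-29.0,-36.6,0.001,27,0.12
P15,59,male,78,24.6,949,8.2,121,14.2,10.4,12.4,-26.8,-12.7,0.013,40,0.18
P16,61,male,90,29.4,1135,9.8,145,17.0,11.9,13.9,-30.0,-18.2,0.012,43,0.20
P17,67,male,67,23.0,724,6.3,92,10.9,9.0,10.0,-17.4,-8.3,0.014,27,0.12
P18,69,male,86,28.7,1003,8.65,128,15.1,10.4,12.1,-31.1,-19.8,0.012,31,0.14
P19,73,male,102,33.7,1135,9.79,145,17.0,11.1,12.5,-34.7,-26.5,0.011,28,0.12
P20,74,male,100,31.9,1130,9.75,144,17.0,11.1,12.1,-34.7,-28.8,0.011,26,0.12
P21,76,male,86,29.8,998,8.61,127,15.0,10.5,11.9,-30.0,-20.7,0.012,23,0.10
P22,77,male,105,40.0,1751,17.36,165,26.3,17.3,13.8,-34.2,-47.5,0.008,25,0.11
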