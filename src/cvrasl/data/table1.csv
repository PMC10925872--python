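patient,age_years,sex,primary_tumor,n_bms,bms_volume_cc,previous_resection,previous_rt,steal_volume_cc,edema_volume_cc
APP001,56,F,Gynecological,3,-,Y,Y,37.03,4.36
APP003,57,F,Lung,7,4.32,N,N,33.41,54.27
APP005,66,M,Melanoma,18,0.87,N,Y,57.81,12.46
APP006,81,M,Melanoma,2,7.09,N,N,40.40,17.10
APP007,62,F,Lung,11,11.20,N,N,74.75,19.46
APP008,72,M,Kidney,1,17.56,N,N,105.29,80.14
APP009,67,M,Lung,8,1.17,N,N,77.20,1.48
APP011,52,F,Lung,8,50.64,N,N,61.71,29.41
APP012,58,M,Melanoma,9,0.67,N,N,28.04,0.30
APP013,75,M,Melanoma,2,9.44,N,N,54.61,1.76
APP016,53,M,Melanoma,2,0.13,N,Y,43.71,-
APP018,72,M,Lung,2,1.75,N,N,38.70,13.19
APP019,65,M,Gastro-intestinal,1,23.85,N,N,81.66,84.43
APP020,75,M,Lung,1,-,Y,N,137.79,16.67
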