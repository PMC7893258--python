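tag_id,uav_id,whale_id,date_iso,location,age_class,sex,n_glides,rho_mean,rho_sd,drag_mean_e6,drag_sd_e6,lssai
Mn16_175a,DAR,H140,2016-06-23,Canada,adult,F,88,1032.9,1.6,10.1,4.2,0.07180
Mn16_178a,HAN,,2016-06-29,Canada,juvenile,F,10,1043.0,8.4,17.5,12.3,0.06629
Mn16_250a,BOO,H494,2016-09-06,Canada,adult,F,28,1036.8,4.7,15.7,4.6,0.07924
Mn16_258a,TRA,H109,2016-09-14,Canada,adult,F,49,1028.8,3.2,16.1,6.4,0.09396
Mn17_022a,HW1,,2017-01-22,Norway,adult (pregnant),F,35,1029.1,1.2,10.8,3.5,0.08181
Mn17_026LLa,HW7,,2017-01-26,Norway,adult (pregnant),F,14,1033.9,3.5,4.3,6.7,0.08713
Mn17_026a,HW8,,2017-01-25,Norway,adult,U,84,1035.4,1.2,7.6,2.5,0.07129
Mn17_158a,FOF,,2017-06-06,Canada,adult,F,83,1030.6,1.8,8.2,4.5,0.08463
Mn17_165a,BOL,H102,2017-06-12,Canada,adult (pregnant),F,131,1032.5,2.2,4.0,6.0,0.07817
Mn17_174a,FAT,H456,2017-06-21,Canada,adult (pregnant),F,177,1034.0,1.5,20.7,4.3,0.07148
Mn17_174b,WIL,H854,2017-06-21,Canada,adult,M,69,1035.2,2.9,11.7,6.1,0.07194
Mn17_178a,FRI,H748,2017-06-25,Canada,adult (pregnant),F,208,1035.0,1.4,20.4,2.1,0.07907
Mn17_178c,PSE,H008,2017-06-24,Canada,adult,F,215,1041.3,2.1,1.6,3.7,0.06810
Mn17_180a,SIA,H007,2017-06-27,Canada,adult,M,133,1037.1,2.2,16.0,3.5,0.06968
Mn17_180b,RAL,H777,2017-06-29,Canada,adult,F,92,1043.6,2.9,20.5,3.9,0.07399
Mn17_184a,EYE,,2017-07-03,Canada,adult,F,103,1038.6,2.6,17.9,3.9,0.06846
Mn17_186b,STL,H152,2017-07-05,Canada,adult,M,101,1038.8,3.0,6.1,4.5,0.06706
Mn17_186c,SPI,H151,2017-07-05,Canada,adult,M,134,1037.6,2.0,10.1,3.4,0.07619
Mn17_186d,FOS,,2017-07-05,Canada,adult,F,68,1031.8,2.2,20.3,4.6,0.07021
Mn17_190a,MAN,H584,2017-07-07,Canada,adult (lactating),F,277,1035.7,1.7,14.4,2.6,0.06477
Mn18_013a,ROL,,2018-01-13,Norway,juvenile,F,41,1042.0,1.7,15.3,2.5,0.08406
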