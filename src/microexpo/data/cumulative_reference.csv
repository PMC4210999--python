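characteristic,subgroup,season,me_group,time_mean,time_sd,mean_pct,mean_pt_cm3,sd_pt_cm3
age,25-34 years,summer,outdoor,0.03,0.01,3.2,610,344
age,25-34 years,summer,in_transit,0.10,0.01,13.5,2567,148
age,25-34 years,summer,indoor,0.88,0.03,83.3,15820,61
age,25-34 years,summer,total,,,100.0,18997,431
age,25-34 years,winter,outdoor,0.03,0.01,2.8,795,359
age,25-34 years,winter,in_transit,0.10,0.01,21.1,5860,823
age,25-34 years,winter,indoor,0.88,0.03,76.1,21113,308
age,25-34 years,winter,total,,,100.0,27768,874
age,35-44 years,summer,outdoor,0.04,0.02,3.6,679,295
age,35-44 years,summer,in_transit,0.08,0.01,12.1,2282,229
age,35-44 years,summer,indoor,0.89,0.02,84.3,15935,1167
age,35-44 years,summer,total,,,100.0,18896,642
age,35-44 years,winter,outdoor,0.04,0.02,2.7,750,183
age,35-44 years,winter,in_transit,0.08,0.01,19.4,5307,1040
age,35-44 years,winter,indoor,0.89,0.02,77.9,21385,1481
age,35-44 years,winter,total,,,100.0,27442,258
age,45-54 years,summer,outdoor,0.03,0.01,2.4,444,175
age,45-54 years,summer,in_transit,0.09,0.01,12.4,2364,92
age,45-54 years,summer,indoor,0.89,0.01,85.2,16244,1283
age,45-54 years,summer,total,,,100.0,19053,1016
age,45-54 years,winter,outdoor,0.03,0.01,2.5,692,247
age,45-54 years,winter,in_transit,0.09,0.01,19.4,5408,642
age,45-54 years,winter,indoor,0.89,0.01,78.2,21856,1347
age,45-54 years,winter,total,,,100.0,27956,458
age,55-59 years,summer,outdoor,0.04,0.02,3.3,644,309
age,55-59 years,summer,in_transit,0.09,0.02,12.4,2466,463
age,55-59 years,summer,indoor,0.89,0.04,84.3,16823,1445
age,55-59 years,summer,total,,,100.0,19933,673
age,55-59 years,winter,outdoor,0.04,0.02,3.0,858,271
age,55-59 years,winter,in_transit,0.09,0.02,20.1,5846,1050
age,55-59 years,winter,indoor,0.89,0.04,76.9,22361,1392
age,55-59 years,winter,total,,,100.0,29064,72
employment,Student,summer,outdoor,0.02,0.03,1.9,402,569
employment,Student,summer,in_transit,0.10,0.02,13.5,2868,431
employment,Student,summer,indoor,0.90,0.01,84.6,17954,392
employment,Student,summer,total,,,100.0,21224,254
employment,Student,winter,outdoor,0.02,0.03,1.7,495,700
employment,Student,winter,in_transit,0.10,0.02,20.7,6100,802
employment,Student,winter,indoor,0.90,0.01,77.6,22791,819
employment,Student,winter,total,,,100.0,29386,922
employment,Employed,summer,outdoor,0.03,0.01,2.5,469,133
employment,Employed,summer,in_transit,0.09,0.01,12.8,2383,165
employment,Employed,summer,indoor,0.89,0.01,84.7,15752,472
employment,Employed,summer,total,,,100.0,18603,175
employment,Employed,winter,outdoor,0.03,0.01,2.3,634,111
employment,Employed,winter,in_transit,0.09,0.01,19.7,5317,776
employment,Employed,winter,indoor,0.89,0.01,78.0,21090,578
employment,Employed,winter,total,,,100.0,27041,309
employment,Self-employed,summer,outdoor,0.04,0.04,3.8,721,684
employment,Self-employed,summer,in_transit,0.10,0.01,13.9,2636,255
employment,Self-employed,summer,indoor,0.88,0.03,82.3,15586,580
employment,Self-employed,summer,total,,,100.0,18943,359
employment,Self-employed,winter,outdoor,0.04,0.04,2.9,847,704
employment,Self-employed,winter,in_transit,0.10,0.01,23.2,6606,1073
employment,Self-employed,winter,indoor,0.88,0.03,73.9,20982,767
employment,Self-employed,winter,total,,,100.0,28435,1010
employment,Housewife,summer,outdoor,0.03,,2.5,559,
employment,Housewife,summer,in_transit,0.08,,10.1,2262,
employment,Housewife,summer,indoor,0.89,,87.4,19564,
employment,Housewife,summer,total,,,100.0,22386,
employment,Housewife,winter,outdoor,0.03,,2.8,873,
employment,Housewife,winter,in_transit,0.08,,16.0,4995,
employment,Housewife,winter,indoor,0.89,,81.2,25377,
employment,Housewife,winter,total,,,100.0,31246,
employment,Retired,summer,outdoor,0.10,,6.8,1516,
employment,Retired,summer,in_transit,0.13,,17.3,3862,
employment,Retired,summer,indoor,0.77,,75.9,16894,
employment,Retired,summer,total,,,100.0,22271,
employment,Retired,winter,outdoor,0.10,,7.8,2561,
employment,Retired,winter,in_transit,0.13,,24.5,8012,
employment,Retired,winter,indoor,0.77,,67.7,22157,
employment,Retired,winter,total,,,100.0,32730,
education,0-9 years,summer,outdoor,0.06,0.05,5.3,1001,850
education,0-9 years,summer,in_transit,0.09,0.01,13.1,2524,276
education,0-9 years,summer,indoor,0.86,0.06,81.6,15823,1914
education,0-9 years,summer,total,,,100.0,19348,788
education,0-9 years,winter,outdoor,0.06,0.05,4.2,1179,785
education,0-9 years,winter,in_transit,0.09,0.01,21.1,6006,1082
education,0-9 years,winter,indoor,0.86,0.06,74.7,21288,2447
education,0-9 years,winter,total,,,100.0,28473,581
education,10-13 years,summer,outdoor,0.03,0.01,3.5,658,294
education,10-13 years,summer,in_transit,0.09,0.01,12.9,2431,233
education,10-13 years,summer,indoor,0.89,0.02,83.7,15841,879
education,10-13 years,summer,total,,,100.0,18929,352
education,10-13 years,winter,outdoor,0.03,0.01,3.1,853,255
education,10-13 years,winter,in_transit,0.09,0.01,19.7,5438,1119
education,10-13 years,winter,indoor,0.89,0.02,77.2,21274,855
education,10-13 years,winter,total,,,100.0,27565,518
education,14-16 years,summer,outdoor,0.03,0.01,3.2,629,251
education,14-16 years,summer,in_transit,0.10,0.01,13.6,2658,110
education,14-16 years,summer,indoor,0.88,0.02,83.2,16277,1042
education,14-16 years,summer,total,,,100.0,19563,681
education,14-16 years,winter,outdoor,0.03,0.01,3.0,869,329
education,14-16 years,winter,in_transit,0.10,0.01,21.7,6201,1112
education,14-16 years,winter,indoor,0.88,0.02,75.2,21428,1174
education,14-16 years,winter,total,,,100.0,28497,267
education,17+ years,summer,outdoor,0.02,0.01,2.2,418,217
education,17+ years,summer,in_transit,0.09,0.01,12.4,2346,149
education,17+ years,summer,indoor,0.90,0.01,85.4,16116,518
education,17+ years,summer,total,,,100.0,18880,153
education,17+ years,winter,outdoor,0.02,0.01,2.0,556,231
education,17+ years,winter,in_transit,0.09,0.01,19.1,5236,397
education,17+ years,winter,indoor,0.90,0.02,78.8,21576,856
education,17+ years,winter,total,,,100.0,27368,228
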