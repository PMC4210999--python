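profile_id,season,me_id,mean_pct,mean_pt_cm3,sd_pt_cm3
male,summer,Bike/Walk,3.8,706,1329
male,summer,Bus/Tram,1.8,345,871
male,summer,Car/Taxi,7.1,1330,2873
male,summer,Motorbike/Scooter,1.8,74,252
male,summer,Train/Metro,,112,290
male,summer,Home Indoor,61.2,11502,12541
male,summer,Home Outdoor,0.3,61,206
male,summer,Work Indoor,13.5,2534,1551
male,summer,Work Outdoor,2.3,430,1432
male,summer,Other Indoor,7.6,1428,2888
male,summer,Other Outdoor,1.5,284,772
male,summer,outdoor,4.1,775,1667
male,summer,in_transit,13.7,2567,3311
male,summer,indoor,82.2,15464,12992
male,summer,total,100.0,18806,13395
male,winter,Bike/Walk,4.8,1324,2221
male,winter,Bus/Tram,1.7,477,1020
male,winter,Car/Taxi,14.4,4027,5523
male,winter,Motorbike/Scooter,7.1,70,213
male,winter,Train/Metro,0.8,221,515
male,winter,Home Indoor,55.9,15581,15996
male,winter,Home Outdoor,0.4,103,342
male,winter,Work Indoor,14.2,3962,2504
male,winter,Work Outdoor,1.6,446,1321
male,winter,Other Indoor,4.5,1247,1791
male,winter,Other Outdoor,1.6,440,1213
male,winter,outdoor,3.5,988,1842
male,winter,in_transit,21.9,6119,6067
male,winter,indoor,74.5,20789,16318
male,winter,total,100.0,27897,17453
female,summer,Bike/Walk,5.1,993,1530
female,summer,Bus/Tram,2.5,478,864
female,summer,Car/Taxi,3.7,713,1339
female,summer,Motorbike/Scooter,0.1,21,119
female,summer,Train/Metro,0.7,140,318
female,summer,Home Indoor,66.4,12866,13271
female,summer,Home Outdoor,0.2,43,138
female,summer,Work Indoor,11.2,2160,1637
female,summer,Work Outdoor,0.4,76,338
female,summer,Other Indoor,8.3,1608,2690
female,summer,Other Outdoor,1.4,265,569
female,summer,outdoor,2.0,383,676
female,summer,in_transit,12.1,2347,2238
female,summer,indoor,85.9,16634,13627
female,summer,total,100.0,19363,13820
female,winter,Bike/Walk,6.5,1791,2143
female,winter,Bus/Tram,2.6,713,1331
female,winter,Car/Taxi,7.7,2134,3064
female,winter,Motorbike/Scooter,0.1,25,214
female,winter,Train/Metro,1.0,265,539
female,winter,Home Indoor,62.5,17273,17293
female,winter,Home Outdoor,0.3,75,221
female,winter,Work Indoor,12.3,3404,2666
female,winter,Work Outdoor,0.3,79,279
female,winter,Other Indoor,5.2,1444,1975
female,winter,Other Outdoor,1.5,420,837
female,winter,outdoor,2.1,574,915
female,winter,in_transit,17.8,4929,3963
female,winter,indoor,80.1,22121,17546
female,winter,total,100.0,27623,18055
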