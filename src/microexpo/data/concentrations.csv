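me_id,category,season,mean_pt_cm3,sd_pt_cm3,sampling_hours
Bike/Walk,in_transit,summer,32214,31679,11.2
Bike/Walk,in_transit,winter,60277,47588,9.7
Bus/Tram,in_transit,summer,36798,30207,6.1
Bus/Tram,in_transit,winter,52386,23821,6.8
Car/Taxi,in_transit,summer,27034,29966,10.8
Car/Taxi,in_transit,winter,82890,53130,10.2
Motorbike/Scooter,in_transit,summer,12016,7898,2.8
Motorbike/Scooter,in_transit,winter,12016,7898,2.8
Train/Metro,in_transit,summer,15730,9126,4.5
Train/Metro,in_transit,winter,30643,13272,2.2
Home Indoor,indoor,summer,21645,21986,1705.8
Home Indoor,indoor,winter,29347,29369,1736.5
Work Indoor,indoor,summer,8849,3917,57.3
Work Indoor,indoor,winter,13865,6364,46.8
Other Indoor,indoor,summer,25694,31743,16.2
Other Indoor,indoor,winter,22148,15309,24.1
Other Outdoor,outdoor,summer,21008,19847,10.0
Other Outdoor,outdoor,winter,32219,24508,10.3
Home Outdoor,outdoor,summer,12722,8820,34.7
Home Outdoor,outdoor,winter,23042,15917,5.6
Work Outdoor,outdoor,summer,18716,18502,6.7
Work Outdoor,outdoor,winter,18880,11524,8.4
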