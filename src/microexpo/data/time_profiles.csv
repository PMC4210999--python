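profile_id,me_id,mean_fraction,sd_fraction
male,Bike/Walk,0.02,0.03
male,Bus/Tram,0.01,0.02
male,Car/Taxi,0.05,0.05
male,Motorbike/Scooter,0.01,0.02
male,Train/Metro,0.01,0.02
male,Home Indoor,0.53,0.08
male,Work Indoor,0.29,0.11
male,Other Indoor,0.06,0.06
male,Other Outdoor,0.01,0.03
male,Home Outdoor,0.00,0.01
male,Work Outdoor,0.02,0.06
female,Bike/Walk,0.03,0.02
female,Bus/Tram,0.01,0.02
female,Car/Taxi,0.03,0.03
female,Motorbike/Scooter,0.00,0.01
female,Train/Metro,0.01,0.02
female,Home Indoor,0.59,0.12
female,Work Indoor,0.24,0.13
female,Other Indoor,0.06,0.06
female,Other Outdoor,0.01,0.02
female,Home Outdoor,0.00,0.01
female,Work Outdoor,0.00,0.02
mean_subject,Bike/Walk,0.029,0
mean_subject,Bus/Tram,0.011,0
mean_subject,Car/Taxi,0.038,0
mean_subject,Motorbike/Scooter,0.003,0
mean_subject,Train/Metro,0.007,0
mean_subject,Home Indoor,0.580,0
mean_subject,Work Indoor,0.005,0
mean_subject,Other Indoor,0.232,0
mean_subject,Other Outdoor,0.012,0
mean_subject,Home Outdoor,0.068,0
mean_subject,Work Outdoor,0.014,0
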