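subject_id,stroke_type,sex,age,acute_day,chronic_day,nihss_initial,fim_initial,fim_6mo,cmsa_hand_initial,cmsa_hand_6mo,cmsa_arm_initial,cmsa_arm_6mo
ST-01,ischemic,M,79,2,242,NaN,109,123,5,6,5,7
ST-03,ischemic,M,37,5,221,11,92,120,1,2,1,3
ST-05,ischemic,M,47,6,206,1,116,125,5,7,7,7
ST-06,ischemic,M,64,4,101,3,105,115,5,5,6,5
ST-08,ischemic,M,62,4,200,2,106,124,6,7,5,7
ST-09,hemorrhagic,F,61,5,191,9,80,124,5,6,4,7
ST-10,ischemic,M,72,6,189,4,96,122,5,6,4,6
ST-16,hemorrhagic,M,62,8,213,10,70,115,5,5,4,5
ST-17,ischemic,M,53,11,221,6,NaN,126,6,6,6,6
ST-19,hemorrhagic,F,78,4,170,4,113,123,7,7,7,7
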