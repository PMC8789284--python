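Type,No.,DRAR7,DRAR8,Sum,%R7,%R8,%Total,%Total_R7,%Total_R8
Dm-DRA1,20,212,0,212,100.0,0.0,15.9,25.3,0.0
Dm9,6,95,115,210,45.2,54.8,15.7,11.3,23.0
MeTu_DRA,29,181,0,181,100.0,0.0,13.5,21.6,0.0
R7_DRA,3,1,108,109,0.9,99.1,8.2,0.1,21.6
Dm-DRA2,9,3,103,106,2.8,97.2,7.9,0.4,20.6
Dm2,4,21,27,48,43.8,56.2,3.6,2.5,5.4
R8_DRA,3,41,1,42,97.6,2.4,3.1,4.9,0.2
Mi15,4,21,18,39,53.8,46.2,2.9,2.5,3.6
Mti_DRA_1,6,37,0,37,100.0,0.0,2.8,4.4,0.0
MeMe_DRA,2,36,0,36,100.0,0.0,2.7,4.3,0.0
L3,3,16,16,32,50.0,50.0,2.4,1.9,3.2
VPN_DRA,6,30,0,30,100.0,0.0,2.2,3.6,0.0
L1,3,9,9,18,50.0,50.0,1.3,1.1,1.8
Tm20,3,0,16,16,0.0,100.0,1.2,0.0,3.2
Mti_DRA_2,4,15,0,15,100.0,0.0,1.1,1.8,0.0
Mi1,3,6,9,15,40.0,60.0,1.1,0.7,1.8
Tm5-like,1,0,12,12,0.0,100.0,0.9,0.0,2.4
Mi9,2,0,12,12,0.0,100.0,0.9,0.0,2.4
MeTu,2,12,0,12,100.0,0.0,0.9,1.4,0.0
Dm11,1,4,8,12,33.3,66.7,0.9,0.5,1.6
MeTu_unknown,1,4,0,4,100.0,0.0,0.3,0.5,0.0
aMe12,1,3,1,4,75.0,25.0,0.3,0.4,0.2
TmY,1,0,3,3,0.0,100.0,0.2,0.0,0.6
ML_VPN2,1,3,0,3,100.0,0.0,0.2,0.4,0.0
C2,1,2,1,3,66.7,33.3,0.2,0.2,0.2
Identified_<3,33,34,14,48,70.8,29.2,3.6,4.1,2.8
Unidentified_>=3,2,5,5,10,50.0,50.0,0.7,0.6,1.0
Unidentified_<3,57,46,21,67,68.7,31.3,5.0,5.5,4.2
Total,211,837,499,1336,62.6,37.4,100.0,100.0,100.0
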