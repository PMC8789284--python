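Type,No.,DRAR7,DRAR8,Sum,%R7,%R8,%Total,%Total_R7,%Total_R8
Dm9,4,105,106,211,49.8,50.2,54.7,46.1,67.1
R8_DRA,3,108,1,109,99.1,0.9,28.2,47.4,0.6
R7_DRA,3,1,41,42,2.4,97.6,10.9,0.4,25.9
C2,2,4,4,8,50.0,50.0,2.1,1.8,2.5
Mi15,1,2,2,4,50.0,50.0,1.0,0.9,1.3
Identified_<3,9,6,3,9,66.7,33.3,2.3,2.6,1.9
Unidentified_>=3,0,0,0,0,0.0,0.0,0.0,0.0,0.0
Unidentified_<3,2,2,1,3,66.7,33.3,0.8,0.9,0.6
Total,24,228,158,386,59.1,40.9,100.0,100.0,100.0
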