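Type,No.,pR7,yR7,pR8,yR8,Sum,%R7,%R8,%p,%y,%Total,%Total_R7,%Total_R8
Dm9,6,90,92,79,72,333,54.7,45.3,50.8,49.2,57.0,51.3,65.9
R8,4,75,82,1,0,158,99.4,0.6,48.1,51.9,27.1,44.2,0.4
R7,4,0,0,31,26,57,0.0,100.0,54.4,45.6,9.8,0.0,24.9
Mt_VPN,1,0,2,0,3,5,40.0,60.0,0.0,100.0,0.9,0.6,1.3
C2,1,2,3,0,0,5,100.0,0.0,40.0,60.0,0.9,1.4,0.0
L3,1,0,0,4,0,4,0.0,100.0,100.0,0.0,0.7,0.0,1.7
Identified_<3,11,4,2,4,8,18,33.3,66.7,44.4,55.6,3.1,1.7,5.2
Unidentified_>=3,0,0,0,0,0,0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Unidentified_<3,4,1,2,1,0,4,75.0,25.0,50.0,50.0,0.7,0.8,0.4
Total,32,172,183,120,109,584,60.8,39.2,50.0,50.0,100.0,100.0,100.0
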