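Type,No.,pR7,yR7,pR8,yR8,Sum,%R7,%R8,%p,%y,%Total,%Total_R7,%Total_R8
Dm9,6,94,66,142,143,445,36.0,64.0,53.0,47.0,16.4,13.5,18.8
Dm8,15,235,161,0,0,396,100.0,0.0,59.3,40.7,14.6,33.4,0.0
MeTu,7,82,93,0,0,175,100.0,0.0,46.9,53.1,6.5,14.7,0.0
R7,5,0,3,75,82,160,1.9,98.1,46.9,53.1,5.9,0.3,10.3
Tm5c,6,8,9,20,103,140,12.1,87.9,20.0,80.0,5.2,1.4,8.1
Tm20,4,5,3,67,65,140,5.7,94.3,51.4,48.6,5.2,0.7,8.7
Mi15,4,6,7,38,81,132,9.8,90.2,33.3,66.7,4.9,1.1,7.8
Mi4,4,0,0,58,58,116,0.0,100.0,50.0,50.0,4.3,0.0,7.6
ML1,4,0,0,58,41,99,0.0,100.0,58.6,41.4,3.7,0.0,6.5
Dm2,4,18,3,60,15,96,21.9,78.1,81.2,18.8,3.5,1.8,4.9
Dm11,2,28,27,4,4,63,87.3,12.7,50.8,49.2,2.3,4.6,0.5
L3,4,19,17,12,13,61,59.0,41.0,50.8,49.2,2.3,3.0,1.6
Mi1,4,0,0,31,28,59,0.0,100.0,52.5,47.5,2.2,0.0,3.9
R8,4,31,26,1,0,58,98.3,1.7,55.2,44.8,2.1,4.8,0.1
Tm5a,2,0,53,0,0,53,100.0,0.0,0.0,100.0,2.0,4.5,0.0
Tm5b,2,39,0,3,6,48,81.2,18.8,87.5,12.5,1.8,3.3,0.6
Tm,9,17,4,7,16,44,47.7,52.3,54.5,45.5,1.6,1.8,1.5
Tm5b-like,3,0,14,0,27,41,34.1,65.9,0.0,100.0,1.5,1.2,1.8
Mi9,4,3,9,26,1,39,30.8,69.2,74.4,25.6,1.4,1.0,1.8
L1,4,2,1,21,14,38,7.9,92.1,60.5,39.5,1.4,0.3,2.3
aMe12,2,4,0,26,0,30,13.3,86.7,100.0,0.0,1.1,0.3,1.7
Dm,5,11,7,6,5,29,62.1,37.9,58.6,41.4,1.1,1.5,0.7
ML_VPN1,3,0,0,26,1,27,0.0,100.0,96.3,3.7,1.0,0.0,1.8
C2,2,7,13,6,0,26,76.9,23.1,50.0,50.0,1.0,1.7,0.4
Mt_VPN,4,0,12,3,8,23,52.2,47.8,13.0,87.0,0.8,1.0,0.7
Mti,3,2,0,10,7,19,10.5,89.5,63.2,36.8,0.7,0.2,1.1
Tm5a-like,1,0,1,0,16,17,5.9,94.1,0.0,100.0,0.6,0.1,1.1
TmY10,1,1,0,6,0,7,14.3,85.7,100.0,0.0,0.3,0.1,0.4
Mi10,1,0,0,0,5,5,0.0,100.0,0.0,100.0,0.2,0.0,0.3
Mi,1,2,1,0,0,3,100.0,0.0,66.7,33.3,0.1,0.3,0.0
C3,1,0,0,0,3,3,0.0,100.0,0.0,100.0,0.1,0.0,0.2
Identified_<3,26,5,14,14,4,37,51.4,48.6,51.4,48.6,1.4,1.6,1.2
Unidentified_>=3,2,0,0,5,3,8,0.0,100.0,62.5,37.5,0.3,0.0,0.5
Unidentified_<3,62,9,15,22,24,70,34.3,65.7,44.3,55.7,2.6,2.0,3.0
Total,211,628,559,747,773,2707,43.8,56.2,50.8,49.2,100.0,100.0,100.0
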