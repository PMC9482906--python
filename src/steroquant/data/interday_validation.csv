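analyte,lloq_nmol_per_l,uloq_nmol_per_l,rsd_high,rsd_mid,rsd_low,rsd_lloq,re_high,re_mid,re_low,re_lloq
11-DOC,0.092,189,5.7,4.7,5.7,10.1,-1.2,-0.2,0.9,0.3
11-deoxycortisol,0.088,180,5.2,6.4,5.8,7.2,-1.3,-4.8,-1.5,-1.9
17OHP4,0.092,189,6.9,8.9,5.7,9.6,-1.9,-1.2,0.2,-5.7
21-deoxycortisol,0.088,180,7.9,7.3,6.3,16.3,-3.5,-2.6,2.2,-6.2
DHT,0.105,215,6.4,5.9,8.1,9.6,-0.6,-1.9,5.7,-8.4
aldosterone,0.085,173,14.9,6.7,9.7,10.3,9.5,3.9,3.3,3.1
A4,0.107,218,5.4,5.2,6.9,7.7,-4.8,0.1,-2.0,6.9
An,0.420,861,9.3,9.4,8.2,10.5,-7.0,-3.7,2.7,8.4
corticosterone,0.705,1443,5.1,7.0,5.3,7.6,0.2,-3.3,2.3,9.8
cortisol,0.378,8967,8.3,10.3,7.6,14.6,2.2,0.9,-1.9,5.6
cortisone,0.177,1387,5.9,5.6,5.2,4.6,-0.2,-2.9,0.9,5.5
DHEA,0.846,867,10.8,8.0,12.8,16.6,0.1,-1.4,2.7,9.6
DHEA-S,6.252,12805,8.8,7.4,7.5,7.0,2.1,7.4,4.3,4.6
Etio,0.210,215,6.5,6.0,6.1,16.6,-3.7,0.0,1.9,0.6
P5,0.771,790,5.5,6.1,9.3,8.5,-0.2,-5.9,7.7,-5.9
P4,0.476,1590,6.2,5.2,4.5,6.3,0.3,-2.2,1.7,2.9
T,0.105,867,6.2,6.2,5.8,7.4,-3.2,-3.8,-1.1,3.9
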