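site,sample,distance_m,zone,temperature_C,pH,conductivity_uScm,o2_mgL,no3_mgL,no2_mgL,so4_mgL,nh4_mgL,hs_ugL
Bison Pool,BP1,2.9,C,89.0,7.23,1550,0.2,0.01,0.02,13.11,0.07,230
Bison Pool,BP2,8.2,C,80.9,7.34,1568,0.7,0.01,0.04,15.43,0.06,220
Bison Pool,BP3,11.1,T,73.3,7.27,1540,1.1,0.02,0.01,16.81,0.04,bdl
Bison Pool,BP4,13.4,P,63.1,8.09,,2.3,0.03,0.02,16.50,0.02,6
Bison Pool,BP5,17.2,P,40.5,8.25,1508,5.7,0.004,bdl,17.18,0.01,15
Bison Pool,BP6,22.6,P,29.0,9.01,1697,3.3,0.07,bdl,18.32,0.02,10
Mound Spring,MS1,3.6,C,91.0,8.81,1612,0.4,0.01,bdl,14.33,0.07,716
Mound Spring,MS2,12.7,C,77.3,8.65,1621,2.2,0.01,bdl,15.03,0.01,758
Mound Spring,MS3,24.2,P,64.8,9.08,1617,1.4,0.04,0.02,16.99,0.03,236
Mound Spring,MS4,38.7,P,53.0,9.22,1634,3.6,0.02,0.01,17.56,0.02,70
Mound Spring,MS5,53,P,35.1,9.53,1660,6.9,0.06,bdl,20.11,bdl,bdl
Empress Pool,EP1,2.2,C,82.2,5.78,1824,0.4,0.01,0.08,106.87,0.42,260
Empress Pool,EP2,6.2,T,70.5,6.96,1832,0.7,,,,,97
Empress Pool,EP3,13.3,T,60.7,7.63,1840,1.2,0.01,bdl,106.70,0.31,37
Empress Pool,EP4,34.8,P,51.6,7.99,1860,1.3,0.03,0.03,111.70,0.39,31
Empress Pool,EP5,37.6,P,38.1,8.42,1664,3.4,0.08,0.01,111.24,0.14,18
Octopus Spring,OS1,7.0,C,85.4,7.29,1622,0.5,0.03,0.03,17.82,0.06,13
Octopus Spring,OS2,38.3,P,59.8,8.27,1581,3.3,0.03,0.02,18.76,0.02,12
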