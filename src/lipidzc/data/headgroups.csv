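code,formula,category
1G,C6H11O5,glycolipid
2G,C12H21O10,glycolipid
3G,C18H31O15,glycolipid
2G-NAcG-G,C24H41NO19,glycolipid
3G-NAcG-G,C30H51NO24,glycolipid
4G,C24H41O20,glycolipid
GA,C6H9O6,glycolipid
G-GA,C12H19O11,glycolipid
G-NG,C12H22NO9,glycolipid
NG-GA,C12H20NO10,glycolipid
SQ,C6H11O7S,glycolipid
1G-P,C6H12O8P,glycophospholipid
2G-P,C12H22O13P,glycophospholipid
3G-P,C18H32O18P,glycophospholipid
G-MeNG-G-P,C19H35NO17P,glycophospholipid
G-NG-G-P,C18H33NO17P,glycophospholipid
MeNG-G-P,C13H25NO12P,glycophospholipid
NAcG-P,C12H21N2O10P,glycophospholipid
NG-G-P,C12H23NO12P,glycophospholipid
PI,C6H12O8P,glycophospholipid
APT,C5H13NO6P,phospholipid
DPG,C3H8O7P2,phospholipid
PC,C5H14NO3P+,phospholipid
PDME,C4H11NO3P,phospholipid
PE,C2H7NO3P,phospholipid
PG,C3H8O5P,phospholipid
PME,C3H9NO3P,phospholipid
PS,C3H7NO5P,phospholipid
BL,C7H15NO2+,aminolipid
OL,C5H10NO2,aminolipid
TM-KL,C9H19NO2+,aminolipid
TM-OL,C8H17NO2+,aminolipid
223,C7H12NO6,unidentified
H,H,other
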