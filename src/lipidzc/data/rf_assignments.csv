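headgroup,backbone,standard
1G,DEG,1
1G,AEG,1
1G,DAG,1
1G,GDGT,2
1G,CER,3
2G,DEG,4
2G,AEG,4
2G,DAG,4
2G,GDGT,2
3G,DEG,4
3G,DAG,4
3G,GDGT,2
2G-NAcG-G,DAG,3
2G-NAcG-G,DEG,3
3G-NAcG-G,DEG,3
4G,GDGT,2
GA,DAG,1
G-GA,DAG,4
G-NG,DAG,3
G-NG,DEG,3
NG-GA,DAG,3
NG-GA,AEG,3
NG-GA,DEG,3
SQ,DAG,5
1G-P,GDGT,2
2G-P,DEG,6
2G-P,GDGT,2
3G-P,GDGT,2
G-MeNG-G-P,DEG,3
G-NG-G-P,DEG,3
MeNG-G-P,DEG,3
NAcG-P,DAG,3
NAcG-P,DEG,3
NG-G-P,DEG,3
PI,DAG,6
PI,AEG,6
PI,DEG,6
PI,CER,3
APT,DEG,3
APT,AEG,3
APT,DAG,3
DPG,DAG,7
PC,DAG,3
PDME,DAG,8
PE,DAG,9
PE,DEG,9
PE,CER,9
PG,DAG,10
PME,DAG,11
PS,DAG,12
BL,DAG,13
OL,FA-OH-FAm,13
OL,FA-OH-FAm-OH,13
TM-KL,FA-OH-FAm,13
TM-OL,FA-OH-FAm,13
TM-OL,FA-OH-FAm-OH,13
223,DAG,3
H,GDGT,2
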