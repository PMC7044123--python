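class,formula,n_backbones,linkages
DAG,C3H5O3,1,ester|ester
DEG,C3H5O3,1,ether|ether
AEG,C3H5O3,1,ester|ether
GDGT,C3H5O3,2,half|half|half|half
DPG,C3H5O3,2,ester|ester|ester|ester
CER,C3H6NO2,1,amide|cc
DIOL,C3H6O2,1,ester|cc
FA-OH-FAm,C3H4NO2,1,ester|cc
FA-OH-FAm-OH,C3H4NO3,1,ester|cc
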