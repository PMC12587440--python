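name,Tm_onset_C,dfusH_kJ_mol,dfusCp_a,dfusCp_b
FEL,141.7,30.4,89.9,0
GRI,218.7,37.9,93.8,0
IBU,75.8,26.4,176.2,-0.3
IND,160.2,38.1,238.2,0.3
NAP,156.0,32.4,99.3,0
NIF,172.6,39.3,121.22,0
PCM,168.2,27.1,99.8,0
PZQ,135.6,23.6,103.3,0
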