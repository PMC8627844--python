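dimension,level,decrement,se,sample
MO,2,0.073,0.008,analytic
MO,3,0.146,0.014,analytic
MO,4,0.245,0.013,analytic
MO,5,0.376,0.012,analytic
SC,2,0.068,0.007,analytic
SC,3,0.110,0.012,analytic
SC,4,0.240,0.012,analytic
SC,5,0.354,0.012,analytic
UA,2,0.060,0.006,analytic
UA,3,0.081,0.012,analytic
UA,4,0.243,0.011,analytic
UA,5,0.306,0.012,analytic
PD,2,0.082,0.006,analytic
PD,3,0.138,0.014,analytic
PD,4,0.580,0.012,analytic
PD,5,0.798,0.013,analytic
AD,2,0.050,0.006,analytic
AD,3,0.127,0.012,analytic
AD,4,0.235,0.012,analytic
AD,5,0.282,0.011,analytic
MO,2,0.075,0.008,full
MO,3,0.144,0.013,full
MO,4,0.243,0.012,full
MO,5,0.376,0.012,full
SC,2,0.071,0.007,full
SC,3,0.121,0.012,full
SC,4,0.239,0.012,full
SC,5,0.346,0.011,full
UA,2,0.064,0.007,full
UA,3,0.075,0.011,full
UA,4,0.247,0.011,full
UA,5,0.290,0.012,full
PD,2,0.090,0.006,full
PD,3,0.139,0.013,full
PD,4,0.570,0.012,full
PD,5,0.788,0.012,full
AD,2,0.057,0.006,full
AD,3,0.140,0.012,full
AD,4,0.241,0.011,full
AD,5,0.281,0.011,full
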