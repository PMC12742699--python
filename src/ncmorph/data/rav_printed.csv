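index_name,k,d,multiplier
CL/CW,-0.1223,1.2597,1.1496
dAN/CS,0.2193,0.1921,0.3895
EL/CS,-0.0539,0.3693,0.3207
HTL/CS,-0.1818,1.0808,0.9172
MGr/CS,-0.0255,0.0430,0.0200
ML/CS,0.0220,1.4492,1.4690
MW/CS,0.1484,0.5459,0.6795
NOL/CS,-0.0127,0.1488,0.1374
PeSH/CS,0.0769,0.1790,0.2482
PeW/CS,0.1097,0.2360,0.3347
PreOc/CL,0.1009,0.4478,0.5386
PrGr/CS,0.0250,0.0011,0.0236
SL/CS,-0.3655,1.1843,0.8553
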