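colobopsis_class,n_sites,Do_quadripunctatus,Cr_scutellaris,Cr_schmidti,Cr_ionia_sl
truncata,33,32,15,5,2
imitans_truncata_like,9,9,1,8,2
imitans_red_headed,8,0,8,0,0
imitans_blackish,10,1,0,1,10
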