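variable,a,b,c,d
female_by_arm,6,4,8,2
university_degree,10,0,10,0
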