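variable,group,n,mean,sd
age,performance,10,48.3,6.17
age,control,10,39.2,11.31
start_age,performance,10,6.6,1.71
start_age,control,10,5.7,1.64
practice_hours,performance,10,5.3,0.82
practice_hours,control,10,4.3,2.06
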