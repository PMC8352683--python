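male,fever,ulcer,pain,aching and limp,nasal congestion,diarrhea,bleeding,tumor,drowsiness,face yellowing,disease
1,1,1,1,0,0,0,0,1,0,0,10111
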