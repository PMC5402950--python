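gender	difference,age,ethnic,effect,issue,significant,race,role,between,class
female	both,participate,voice,bodily,figure,student,male,than,athlete,first
male	young,black,white
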