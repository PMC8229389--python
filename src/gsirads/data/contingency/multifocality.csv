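rater_a,rater_b,count
no,no,1165
no,yes,57
yes,no,111
yes,yes,263
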