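rater_a,rater_b,count
no,no,1110
no,yes,17
yes,no,56
yes,yes,413
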