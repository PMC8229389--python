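rater_a,rater_b,count
left,left,782
left,right,2
left,none,10
right,left,3
right,right,789
right,none,7
none,left,0
none,right,1
none,none,2
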