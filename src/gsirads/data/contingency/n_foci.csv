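rater_a,rater_b,count
0,0,2
0,1,1
0,2,0
0,3,0
0,4,0
0,5,0
1,0,13
1,1,1149
1,2,52
1,3,5
1,4,0
1,5,0
2,0,4
2,1,86
2,2,148
2,3,16
2,4,1
2,5,0
3,0,0
3,1,19
3,2,32
3,3,36
3,4,2
3,5,0
4,0,0
4,1,1
4,2,8
4,3,7
4,4,3
4,5,1
5,0,0
5,1,1
5,2,2
5,3,2
5,4,2
5,5,0
6,0,0
6,1,0
6,2,0
6,3,0
6,4,1
6,5,0
7,0,0
7,1,0
7,2,0
7,3,0
7,4,0
7,5,1
11,0,0
11,1,0
11,2,0
11,3,0
11,4,0
11,5,1
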