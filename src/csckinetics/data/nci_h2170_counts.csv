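day,count_millions,irradiated
2,2.78,0
3,3.24,0
4,4.32,0
6,8.27,0
9,21.2,0
2,2.16,1
6,4.62,1
9,9.38,1
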