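class,c1,c2,c3,c4,c5,c6,c7
c1,58,0,15,0,0,0,5
c2,0,18,1,4,0,4,1
c3,11,0,143,0,1,5,17
c4,0,4,5,18,0,2,6
c5,1,1,1,0,31,1,1
c6,0,6,9,7,2,76,4
c7,20,0,23,0,2,4,94
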