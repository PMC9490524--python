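item,question,n1,n2,n3,n4,n5
1,I think that I would like to use this system frequently,0,0,0,7,33
2,I found the system unnecessarily complex,40,0,0,0,0
3,I thought the system was easy to use,0,0,0,11,29
4,I think that I would need the support of a technical person to be able to use this system,30,10,0,0,0
5,I found the various functions in this system were well integrated,0,0,0,16,24
6,I thought there was too much inconsistency in this system,40,0,0,0,0
7,I would imagine that most people would learn to use this system very quickly,0,0,0,3,37
8,I found the system very cumbersome to use,34,6,0,0,0
9,I felt very confident using the system,0,0,2,8,30
10,I needed to learn a lot of things before I could get going with this system,35,5,0,0,0
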