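bin	start	end
A	1	336
B	337	765
C	766	1000
D	1001	1260
E	1261	1600
F	1601	2000
G	2001	2400
H	2401	2842
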