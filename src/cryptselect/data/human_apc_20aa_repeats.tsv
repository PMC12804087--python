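repeat	start	end
1	1262	1281
2	1376	1395
3	1486	1505
4	1577	1596
5	1857	1876
6	2009	2028
7	2052	2071
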