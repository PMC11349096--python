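index,x_deg,y_deg,is_blind_spot
0,-9,21,False
1,-3,21,False
2,3,21,False
3,9,21,False
4,-15,15,False
5,-9,15,False
6,-3,15,False
7,3,15,False
8,9,15,False
9,15,15,False
10,-21,9,False
11,-15,9,False
12,-9,9,False
13,-3,9,False
14,3,9,False
15,9,9,False
16,15,9,False
17,21,9,False
18,-27,3,False
19,-21,3,False
20,-15,3,False
21,-9,3,False
22,-3,3,False
23,3,3,False
24,9,3,False
25,15,3,True
26,21,3,False
27,-27,-3,False
28,-21,-3,False
29,-15,-3,False
30,-9,-3,False
31,-3,-3,False
32,3,-3,False
33,9,-3,False
34,15,-3,True
35,21,-3,False
36,-21,-9,False
37,-15,-9,False
38,-9,-9,False
39,-3,-9,False
40,3,-9,False
41,9,-9,False
42,15,-9,False
43,21,-9,False
44,-15,-15,False
45,-9,-15,False
46,-3,-15,False
47,3,-15,False
48,9,-15,False
49,15,-15,False
50,-9,-21,False
51,-3,-21,False
52,3,-21,False
53,9,-21,False
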