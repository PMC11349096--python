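index,x_deg,y_deg,is_blind_spot
0,-9,27,False
1,-3,27,False
2,3,27,False
3,9,27,False
4,-15,21,False
5,-9,21,False
6,-3,21,False
7,3,21,False
8,9,21,False
9,15,21,False
10,-21,15,False
11,-15,15,False
12,-9,15,False
13,-3,15,False
14,3,15,False
15,9,15,False
16,15,15,False
17,21,15,False
18,-27,9,False
19,-21,9,False
20,-15,9,False
21,-9,9,False
22,-3,9,False
23,3,9,False
24,9,9,False
25,15,9,False
26,21,9,False
27,27,9,False
28,-27,3,False
29,-21,3,False
30,-15,3,False
31,-9,3,False
32,-3,3,False
33,3,3,False
34,9,3,False
35,15,3,True
36,21,3,False
37,27,3,False
38,-27,-3,False
39,-21,-3,False
40,-15,-3,False
41,-9,-3,False
42,-3,-3,False
43,3,-3,False
44,9,-3,False
45,15,-3,True
46,21,-3,False
47,27,-3,False
48,-27,-9,False
49,-21,-9,False
50,-15,-9,False
51,-9,-9,False
52,-3,-9,False
53,3,-9,False
54,9,-9,False
55,15,-9,False
56,21,-9,False
57,27,-9,False
58,-21,-15,False
59,-15,-15,False
60,-9,-15,False
61,-3,-15,False
62,3,-15,False
63,9,-15,False
64,15,-15,False
65,21,-15,False
66,-15,-21,False
67,-9,-21,False
68,-3,-21,False
69,3,-21,False
70,9,-21,False
71,15,-21,False
72,-9,-27,False
73,-3,-27,False
74,3,-27,False
75,9,-27,False
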