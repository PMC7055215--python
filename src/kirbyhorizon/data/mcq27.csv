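index,immediate,delayed,delay_days,bin
1,54,55,117,medium
2,55,75,61,large
3,19,25,53,small
4,31,85,7,large
5,14,25,19,small
6,47,50,160,medium
7,15,35,13,small
8,25,60,14,medium
9,78,80,162,large
10,40,55,62,medium
11,11,30,7,small
12,67,75,119,large
13,34,35,186,small
14,27,50,21,medium
15,69,85,91,large
16,49,60,89,medium
17,80,85,157,large
18,24,35,29,small
19,33,80,14,large
20,28,30,179,small
21,34,50,30,medium
22,25,30,80,small
23,41,75,20,large
24,54,60,111,medium
25,54,80,30,large
26,22,25,136,small
27,20,55,7,medium
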