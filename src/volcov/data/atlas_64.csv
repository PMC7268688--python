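index,name,hemisphere,label_code
1,Thalamus,Left,1
2,Thalamus,Right,2
3,Putamen,Left,3
4,Putamen,Right,4
5,Globus pallidus,Left,5
6,Globus pallidus,Right,6
7,Caudate nucleus,Left,7
8,Caudate nucleus,Right,8
9,Superior frontal gyrus,Left,9
10,Superior frontal gyrus,Right,10
11,Middle frontal gyrus,Left,11
12,Middle frontal gyrus,Right,12
13,Inferior frontal gyrus,Left,13
14,Inferior frontal gyrus,Right,14
15,Medial fronto-orbital gyrus,Left,15
16,Medial fronto-orbital gyrus,Right,16
17,Lateral fronto-orbital gyrus,Left,17
18,Lateral fronto-orbital gyrus,Right,18
19,Gyrus rectus,Left,19
20,Gyrus rectus,Right,20
21,Precentral gyrus,Left,21
22,Precentral gyrus,Right,22
23,Postcentral gyrus,Left,23
24,Postcentral gyrus,Right,24
25,Superior parietal gyrus,Left,25
26,Superior parietal gyrus,Right,26
27,Precuneus,Left,27
28,Precuneus,Right,28
29,Cingular gyrus,Left,29
30,Cingular gyrus,Right,30
31,Supramarginal gyrus,Left,31
32,Supramarginal gyrus,Right,32
33,Angular gyrus,Left,33
34,Angular gyrus,Right,34
35,Superior temporal gyrus,Left,35
36,Superior temporal gyrus,Right,36
37,Middle temporal gyrus,Left,37
38,Middle temporal gyrus,Right,38
39,Inferior temporal gyrus,Left,39
40,Inferior temporal gyrus,Right,40
41,Fusiform gyrus,Left,41
42,Fusiform gyrus,Right,42
43,Parahippocampal gyrus,Left,43
44,Parahippocampal gyrus,Right,44
45,Entorhinal cortex,Left,45
46,Entorhinal cortex,Right,46
47,Superior occipital gyrus,Left,47
48,Superior occipital gyrus,Right,48
49,Middle occipital gyrus,Left,49
50,Middle occipital gyrus,Right,50
51,Inferior occipital gyrus,Left,51
52,Inferior occipital gyrus,Right,52
53,Cuneus,Left,53
54,Cuneus,Right,54
55,Lingual gyrus,Left,55
56,Lingual gyrus,Right,56
57,Amygdala,Left,57
58,Amygdala,Right,58
59,Hippocampus,Left,59
60,Hippocampus,Right,60
61,Cerebellar hemisphere,Left,61
62,Cerebellar hemisphere,Right,62
63,Insular cortex,Left,63
64,Insular cortex,Right,64
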