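item_id,stem,wording,dif,discrimination,t1,t2,t3,occasion
1,Could concentrate,positive,0,1.01,-3.42,1.88,3.99,
2,Lost sleep,negative,0,1.38,-0.41,2.74,5.06,
3,Restless nights,negative,0,0.43,-0.43,0.89,1.82,
4,Busy or occupied,positive,0,0.38,-1.41,2.56,3.95,
5,Out of the house,positive,0,0.51,-1.84,1.99,3.53,
6,Managing well,positive,0,0.68,-1.36,3.51,4.96,
7,Doing things well,positive,0,1.30,-3.02,3.91,6.86,
8,Satisfied with task,positive,0,1.24,-2.84,3.84,6.76,
9,Feel warmth and affection,positive,0,0.44,-1.47,2.69,4.17,
10,Get on with others,positive,0,0.59,-2.41,3.27,5.09,
11,Chatting with others,positive,0,0.43,-1.70,2.30,3.99,
12,Playing a useful part,positive,0,0.82,-2.16,2.36,4.16,
13,Capable make decisions,positive,0,0.54,-1.60,1.77,3.26,
14,Felt under strain,negative,0,1.93,-1.39,2.19,5.12,
15,Could not overcome difficulties,negative,0,2.05,-0.41,3.18,5.30,
16,Found life a struggle,negative,1,0.81,-0.62,2.02,3.21,
17,Enjoying activities,positive,0,0.62,-1.73,1.20,2.28,
18,Taking things hard,negative,0,1.71,-0.87,2.46,4.69,
19,Scared or panicky,negative,1,1.02,0.13,2.55,3.74,
20,Face problems,positive,0,0.98,-2.67,2.75,4.42,
21,Felt everything on top,negative,0,2.96,-0.66,3.50,7.14,
22,Unhappy and depressed,negative,0,2.87,-0.20,2.99,6.05,
23,Lost confidence,negative,0,2.96,0.34,3.67,6.58,
24,Felt worthless,negative,0,2.83,1.84,4.61,6.75,
25,Felt life hopeless,negative,1,1.37,0.97,2.70,4.48,
26,Hopeful about future,positive,0,0.90,-1.66,2.21,3.74,
27,Feeling happy,positive,0,0.72,-1.60,1.65,2.94,
28,Nervous and strung up,negative,0,2.62,0.46,3.69,6.63,
29,Felt life not worth living,negative,0,2.78,3.02,5.40,7.10,
30,Nerves too bad,negative,0,2.35,2.65,5.02,6.55,
16,Found life a struggle,negative,1,3.29,-1.27,4.14,7.86,followup
19,Scared or panicky,negative,1,2.54,0.20,4.05,6.63,followup
25,Felt life hopeless,negative,1,1.81,1.10,3.08,4.10,followup
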