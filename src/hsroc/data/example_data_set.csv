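study_name,TP,FN,FP,TN
1,90,10,20,80
2,40,10,5,45
3,60,40,10,90
4,200,50,100,200
5,10,5,5,15
6,80,20,10,90
7,60,40,30,70
8,8,2,1,9
9,250,50,100,200
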