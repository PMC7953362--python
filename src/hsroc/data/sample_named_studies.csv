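study_name,TP,FN,FP,TN
1995-Andrew,90,10,20,80
1998-Philips,40,10,5,45
2003-Lee,60,40,10,90
2008-Yamada,200,50,100,200
2013-Lewis,10,5,5,15
2014-Williams,80,20,10,90
2015-Wang,60,40,30,70
2016-Cooper,8,2,1,9
2018-Dunphy,250,50,100,200
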