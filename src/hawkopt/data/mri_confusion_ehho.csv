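dataset,class,TP,FP,TN,FN,TPR,TNR,PPV,NPV,FPR,FNR,FDR,ACC,F1
dataset1,Normal,487,38,1462,13,0.974,0.974,0.928,0.991,0.025,0.026,0.072,0.974,0.950
dataset1,Grade II,473,16,1484,27,0.946,0.989,0.967,0.982,0.011,0.054,0.033,0.979,0.957
dataset1,Grade III,473,18,1482,27,0.946,0.988,0.963,0.982,0.012,0.054,0.037,0.978,0.955
dataset1,Grade IV,479,16,1484,21,0.958,0.989,0.967,0.986,0.011,0.042,0.032,0.982,0.963
dataset2,Glioma,111,4,226,4,0.965,0.983,0.965,0.983,0.017,0.035,0.035,0.977,0.965
dataset2,Meningioma,113,3,227,2,0.983,0.987,0.974,0.991,0.013,0.017,0.026,0.986,0.978
dataset2,Pituitary,113,1,229,2,0.983,0.996,0.991,0.991,0.004,0.017,0.009,0.991,0.987
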