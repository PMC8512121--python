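dataset,class,TP,FP,TN,FN,TPR,TNR,PPV,NPV,FPR,FNR,FDR,ACC,F1
dataset1,Normal,474,52,1448,26,0.948,0.965,0.901,0.982,0.035,0.052,0.099,0.961,0.924
dataset1,Grade II,471,33,1467,29,0.942,0.978,0.935,0.981,0.022,0.058,0.065,0.969,0.938
dataset1,Grade III,452,27,1473,48,0.904,0.982,0.944,0.968,0.018,0.096,0.056,0.963,0.924
dataset1,Grade IV,463,28,1472,37,0.926,0.981,0.943,0.975,0.019,0.074,0.057,0.967,0.934
dataset2,Glioma,110,8,222,5,0.957,0.965,0.932,0.978,0.035,0.043,0.068,0.962,0.944
dataset2,Meningioma,111,4,226,4,0.965,0.983,0.965,0.983,0.017,0.035,0.035,0.977,0.965
dataset2,Pituitary,111,1,229,4,0.965,0.996,0.991,0.983,0.004,0.035,0.009,0.986,0.978
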