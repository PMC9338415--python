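study,paradigm,subscale,n,pre_mean,pre_sd,post_mean,post_sd,change_mean,change_sd,t,df,p,d_printed
DST,DST,NA,103,1.57,0.56,1.84,0.70,0.27,0.61,-4.51,102,<.001,0.427
DST,DST,PA,103,3.08,0.65,3.37,0.85,0.29,0.61,-4.84,102,<.001,0.382
TSST-1,TSST,NA,26,1.28,0.38,1.82,0.66,0.55,0.68,-4.08,25,<.001,1.015
TSST-1,TSST,PA,26,2.95,0.45,2.94,0.59,-0.01,0.51,0.11,25,.91,0.022
TSST-2,TSST,NA,26,1.33,0.32,1.66,0.57,0.32,0.44,-3.75,25,<.001,0.694
TSST-2,TSST,PA,26,2.95,0.56,2.97,0.64,0.02,0.45,-0.17,25,.86,0.026
TSST-3,TSST,NA,20,1.36,0.33,1.51,0.71,0.16,0.68,-1.02,19,.32,0.281
TSST-3,TSST,PA,20,2.75,0.42,3.02,0.96,0.27,0.82,-1.47,19,.16,0.363
TSST-4,TSST,NA,50,1.43,0.56,1.85,0.72,0.42,0.53,-5.64,49,<.001,0.655
TSST-4,TSST,PA,50,3.02,0.57,2.88,0.68,-0.14,0.47,2.10,49,.04,0.221
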