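region,lat,tavg_veg,tacc15_veg,dtr_veg,prec_veg,srad_veg,tavg_rep,tacc15_rep,dtr_rep,prec_rep,srad_rep
1,49.55,13.92,496.48,13.71,123.15,20831.60,16.09,1152.07,12.48,324.39,16827.97
2,46.09,16.17,647.31,11.95,128.94,20870.56,18.75,1393.13,11.31,319.65,17483.93
3,42.49,17.89,934.92,11.64,137.17,21257.63,20.55,1785.42,11.88,372.49,18018.56
4,36.33,20.40,1181.04,12.08,111.98,21729.14,22.16,1971.41,11.15,349.50,18684.50
5,32.21,26.89,1236.98,9.63,260.16,20194.97,25.02,1526.49,9.97,229.66,18261.92
6,27.70,27.22,1252.21,8.58,255.22,20136.46,25.95,1583.04,9.10,234.48,18852.77
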