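ancestry_group,mg_min,mg_max,provinces,region,scenarios
K10.7,000,0,,1,A
K10.7,I,I,,2,A
K10.8,I,I,,2,B
K10.7,II,III,,3,A
K10.8,II,III,,3,B
K10.5,,,,4,AB
K10.6,,,Anhui;Henan;Hubei;Jiangsu;Shanghai,5,AB
K10.6,,,Fujian;Hunan;Jiangxi;Zhejiang,6,AB
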