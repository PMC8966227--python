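case_id,citation,age_years,sex,exposure_type,substance,dose_g,serum_ng_ml,co_ingestants,vt_vf,qrs_ms,qt_ms,qtc_ms,hr_bpm
1,Bin Salih et al.,20,F,intoxication,citalopram,1.8,,Ethanol,false,82,428,494,80
2,Lung et al.,21,M,intoxication,citalopram,11.6,522,Olanzapine;Clonazepam,false,160,400,487,85
3,Venkatraman et al.,23,F,intoxication,citalopram,0.22,,Lamotrigine;Chlorphenamine;Ethanol,false,120,352,470,107
4,Cuenca et al.,23,M,intoxication,citalopram,0.92,,,false,108,446,446,60
5,Lung et al.,24,F,intoxication,citalopram,1.8,400,Bupropion;Clonazepam,true,85,411,515,93
6,Farkas et al.,25,F,intoxication,escitalopram,,290,Lamotrigine,false,98,392,496,96
7,Engebretsen et al.,31,M,intoxication,citalopram,0.4,1940,Ethanol,false,124,344,506,130
8,Mohammed et al.,33,F,intoxication,escitalopram,0.4,,Lithium,false,117,479,491,63
9,Kraai et al.,35,F,intoxication,citalopram,,7300,Cannabis,true,92,360,502,117
10,Deshmukh et al.,40,F,therapeutic,citalopram,0.08,,,true,74,357,535,90
11,Gregorio et al.,48,F,therapeutic,citalopram,0.04,,Furosemide,true,83,620,670,75
12,Baranchuk et al.,52,M,intoxication,escitalopram,0.14,,Diazepam;Zopiclone;Lorazepam;Morphine,false,145,727,650,48
13,Liotier et al.,54,F,intoxication,citalopram,,,Ethanol,true,83,600,670,75
14,Kanjanauthai et al.,81,M,therapeutic,citalopram,,,,true,92.5,572,695,83
15,Brucculeri et al.,82,F,intoxication,citalopram,1.6,910,,false,146,544,534,58
16,Agosti et al.,89,F,therapeutic,citalopram,0.04,,Levosulpiride,true,122,650,657,59
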