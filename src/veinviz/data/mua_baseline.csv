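wavelength_nm,value
400,2.319417566
410,2.028440585
420,1.778259058
430,1.563153396
440,1.378205905
450,1.219188358
460,1.082465334
470,0.9649111054
480,0.8638381741
490,0.7769358351
500,0.7022173481
510,0.6379745168
520,0.5827386368
530,0.5352469187
540,0.4944136182
550,0.4593052141
560,0.4291190663
570,0.4031650665
580,0.3808498605
590,0.3616632833
600,0.3451666961
610,0.3309829577
620,0.3187878029
630,0.308302429
640,0.299287122
650,0.2915357759
660,0.2848711813
670,0.279140974
680,0.2742141512
690,0.2699780772
700,0.2663359077
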