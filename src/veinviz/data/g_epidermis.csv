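wavelength_nm,value
400,0.736
410,0.7389
420,0.7418
430,0.7447
440,0.7476
450,0.7505
460,0.7534
470,0.7563
480,0.7592
490,0.7621
500,0.765
510,0.7679
520,0.7708
530,0.7737
540,0.7766
550,0.7795
560,0.7824
570,0.7853
580,0.7882
590,0.7911
600,0.794
610,0.7969
620,0.7998
630,0.8027
640,0.8056
650,0.8085
660,0.8114
670,0.8143
680,0.8172
690,0.8201
700,0.823
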