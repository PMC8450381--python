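wavelength_nm,value
400,266232
410,466840
420,480360
430,246072
440,102580
450,62816
460,33209.2
470,27644
480,26629.2
490,23684.8
500,20932.8
510,20035.2
520,24202.4
530,39956.8
540,53236
550,43016
560,32613.2
570,44496
580,50104
590,14400.8
600,3200
610,1506
620,942
630,610
640,442
650,368
660,319.6
670,294
680,277.6
690,276
700,290
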