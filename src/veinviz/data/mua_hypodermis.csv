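wavelength_nm,value
400,0.13
410,0.13
420,0.13
430,0.13
440,0.13
450,0.13
460,0.13
470,0.13
480,0.13
490,0.13
500,0.13
510,0.13
520,0.13
530,0.13
540,0.13
550,0.13
560,0.13
570,0.13
580,0.13
590,0.13
600,0.13
610,0.13
620,0.13
630,0.13
640,0.13
650,0.13
660,0.13
670,0.13
680,0.13
690,0.13
700,0.13
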