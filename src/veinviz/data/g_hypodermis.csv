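wavelength_nm,value
400,0.8
410,0.8
420,0.8
430,0.8
440,0.8
450,0.8
460,0.8
470,0.8
480,0.8
490,0.8
500,0.8
510,0.8
520,0.8
530,0.8
540,0.8
550,0.8
560,0.8
570,0.8
580,0.8
590,0.8
600,0.8
610,0.8
620,0.8
630,0.8
640,0.8
650,0.8
660,0.8
670,0.8
680,0.8
690,0.8
700,0.8
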