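wavelength_nm,value
400,2.781221961e-07
410,2.224977569e-06
420,1.525878906e-05
430,8.970547438e-05
440,0.0004520872619
450,0.001953125
460,0.00723339619
470,0.02296460144
480,0.0625
490,0.1458161299
500,0.2916322599
510,0.5
520,0.7348672461
530,0.9258747123
540,1
550,0.9258747123
560,0.7348672461
570,0.5
580,0.2916322599
590,0.1458161299
600,0.0625
610,0.02296460144
620,0.00723339619
630,0.001953125
640,0.0004520872619
650,8.970547438e-05
660,1.525878906e-05
670,2.224977569e-06
680,2.781221961e-07
690,2.980232239e-08
700,2.737593823e-09
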