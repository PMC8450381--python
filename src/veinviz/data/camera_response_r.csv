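wavelength_nm,value
400,1.776356839e-15
410,4.177236668e-14
420,8.420781453e-13
430,1.455191523e-11
440,2.155720052e-10
450,2.737593823e-09
460,2.980232239e-08
470,2.781221961e-07
480,2.224977569e-06
490,1.525878906e-05
500,8.970547438e-05
510,0.0004520872619
520,0.001953125
530,0.00723339619
540,0.02296460144
550,0.0625
560,0.1458161299
570,0.2916322599
580,0.5
590,0.7348672461
600,0.9258747123
610,1
620,0.9258747123
630,0.7348672461
640,0.5
650,0.2916322599
660,0.1458161299
670,0.0625
680,0.02296460144
690,0.00723339619
700,0.001953125
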