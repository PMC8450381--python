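wavelength_nm,value
400,0.0625
410,0.1458161299
420,0.2916322599
430,0.5
440,0.7348672461
450,0.9258747123
460,1
470,0.9258747123
480,0.7348672461
490,0.5
500,0.2916322599
510,0.1458161299
520,0.0625
530,0.02296460144
540,0.00723339619
550,0.001953125
560,0.0004520872619
570,8.970547438e-05
580,1.525878906e-05
590,2.224977569e-06
600,2.781221961e-07
610,2.980232239e-08
620,2.737593823e-09
630,2.155720052e-10
640,1.455191523e-11
650,8.420781453e-13
660,4.177236668e-14
670,1.776356839e-15
680,6.475536993e-17
690,2.02360531e-18
700,5.421010862e-20
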