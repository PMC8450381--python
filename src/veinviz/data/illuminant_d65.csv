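wavelength_nm,value
400,82.75
410,91.49
420,93.43
430,86.68
440,104.86
450,117.01
460,117.81
470,114.86
480,115.92
490,108.81
500,109.35
510,107.8
520,104.79
530,107.69
540,104.41
550,104.05
560,100
570,96.33
580,95.79
590,88.69
600,90.01
610,89.6
620,87.7
630,83.29
640,83.7
650,80.03
660,80.21
670,82.28
680,78.28
690,69.72
700,71.61
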