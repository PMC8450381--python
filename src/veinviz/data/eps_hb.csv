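wavelength_nm,value
400,223296
410,303956
420,407560
430,528600
440,413280
450,103292
460,23388.8
470,18010
480,16156.4
490,17571.6
500,20862
510,25773.6
520,31589.6
530,39036.4
540,46592
550,52276
560,53788
570,45092
580,37020
590,26600
600,14677.2
610,9443.6
620,7552
630,5763
640,4558
650,3750.12
660,3226.56
670,2795.12
680,2407.92
690,2051.96
700,1794.28
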