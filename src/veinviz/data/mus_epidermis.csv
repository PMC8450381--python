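wavelength_nm,value
400,337.1827399
410,331.2927887
420,325.7708703
430,320.5923983
440,315.7352013
450,311.1792528
460,306.9064369
470,302.9003463
480,299.1461053
490,295.6302163
500,292.3404255
510,289.265605
520,286.3956497
530,283.7213865
540,281.2344949
550,278.9274367
560,276.7933945
570,274.8262173
580,273.0203731
590,271.3709073
600,269.8734059
610,268.5239643
620,267.3191598
630,266.256028
640,265.3320434
650,264.545103
660,263.893513
670,263.3759787
680,262.9915974
690,262.7398541
700,262.6206194
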