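wavelength_nm,value
400,87.28911136
410,85.83567837
420,84.44060745
430,83.10024736
440,81.81125339
450,80.57055532
460,79.37532944
470,78.22297388
480,77.11108695
490,76.0374479
500,75
510,73.99683537
520,73.02618158
530,72.08638965
540,71.17592332
550,70.2933494
560,69.43732919
570,68.60661064
580,67.80002136
590,67.01646231
600,66.25490202
610,65.51437142
620,64.79395911
630,64.09280706
640,63.41010671
650,62.74509538
660,62.09705303
670,61.46529927
680,60.8491906
690,60.24811792
700,59.66150426
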