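wavelength_nm,value
400,266647.1409
410,245598.9239
420,226660.8773
430,209578.5085
440,194132.966
450,180135.3848
460,167422.2303
470,155851.4458
480,145299.2531
490,135657.4833
500,126831.3421
510,118737.5315
520,111302.6663
530,104461.9327
540,98157.95057
550,92339.80358
560,86962.21088
570,81984.81727
580,77371.58324
590,73090.25947
600,69111.93279
610,65410.63298
620,61962.99144
630,58747.94407
640,55746.47219
650,52941.37599
660,50317.07616
670,47859.43964
680,45555.62645
690,43393.9546
700,41363.78091
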