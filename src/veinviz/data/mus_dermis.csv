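wavelength_nm,value
400,228.9296329
410,224.2042459
420,219.7723877
430,215.6132214
440,211.7079852
450,208.0397532
460,204.5932291
470,201.3545677
480,198.31122
490,195.4517981
500,192.7659574
510,190.2442939
520,187.8782535
530,185.660053
540,183.5826105
550,181.6394838
560,179.8248165
570,178.1332902
580,176.5600829
590,175.1008316
600,173.7515997
610,172.5088489
620,171.369414
630,170.3304809
640,169.3895681
650,168.5445107
660,167.7934465
670,167.1348049
680,166.5672981
690,166.0899135
700,165.7019097
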