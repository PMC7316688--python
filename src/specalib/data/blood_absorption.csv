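wavelength_nm,mua_oxy,mua_deoxy
450,336.370,553.113
460,238.269,465.872
470,177.829,385.549
480,142.594,310.581
490,117.807,214.194
500,112.093,111.713
510,107.632,138.011
520,149.936,166.000
530,214.194,214.194
540,285.071,249.493
550,230.344,281.130
560,174.638,288.027
570,238.269,246.323
580,268.299,192.775
590,48.194,128.516
600,17.136,78.593
610,6.961,61.581
620,5.087,49.800
630,3.481,41.232
640,2.570,29.452
650,1.971,20.081
660,1.714,17.280
670,1.606,15.261
680,1.499,13.157
690,1.526,11.245
700,1.553,9.607
710,1.687,8.246
720,1.874,6.961
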