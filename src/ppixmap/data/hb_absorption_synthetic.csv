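wavelength_nm,relative_absorption
400,0.850000
410,1.000000
420,0.800000
430,0.420000
440,0.200000
450,0.115000
460,0.080000
470,0.062000
480,0.052000
490,0.048000
500,0.050000
510,0.054000
520,0.060000
530,0.067000
540,0.070000
550,0.066000
560,0.060000
570,0.062000
580,0.058000
590,0.040000
600,0.028000
610,0.022000
620,0.019000
630,0.018500
640,0.015400
650,0.012000
660,0.009500
670,0.008000
680,0.007000
690,0.006300
700,0.005800
710,0.005400
720,0.005100
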