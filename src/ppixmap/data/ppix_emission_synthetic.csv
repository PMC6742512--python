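wavelength_nm,relative_intensity
600,0.003551
605,0.014774
610,0.049992
615,0.137587
620,0.307982
625,0.560717
630,0.830297
635,1.000000
640,0.979631
645,0.780751
650,0.506775
655,0.269500
660,0.121656
665,0.056507
670,0.045316
675,0.065548
680,0.106106
685,0.160807
690,0.221861
695,0.277722
700,0.315314
705,0.324689
710,0.303235
715,0.256850
720,0.197319
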