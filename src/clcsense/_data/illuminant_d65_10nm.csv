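wavelength_nm,power
380,49.98
390,54.65
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
510,107.80
520,104.79
530,107.69
540,104.41
550,104.05
560,100.00
570,96.33
580,95.79
590,88.69
600,90.01
610,89.60
620,87.70
630,83.29
640,83.70
650,80.03
660,80.21
670,82.28
680,78.28
690,69.72
700,71.61
710,74.35
720,61.60
730,69.89
740,75.09
750,63.59
760,46.42
770,66.81
780,63.38
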