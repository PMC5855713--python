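# Synthetic molar extinction spectra of human hemoglobin, 400-700 nm at 10 nm.
# Reconstructed from widely published landmark values (Soret maxima near
# 414/430 nm, Q-bands at 542/577 nm for HbO2 and 555 nm for Hb, isosbestic
# points near 500 and 570 nm, red-tail values used in pulse oximetry).
# NOT a verbatim copy of any tabulation; intended for self-consistent
# simulation and estimation within this package only.
# Units: cm^-1 / (mol/L).
wavelength_nm,eps_hbo2,eps_hb
400,266000,223000
410,467000,304000
420,340000,408000
430,120000,529000
440,62000,413000
450,42000,216000
460,29000,112000
470,24000,60000
480,21000,37000
490,20500,26500
500,20900,20900
510,20500,22500
520,26000,27500
530,40000,35500
540,53000,44000
550,43000,51000
560,32600,53400
570,45000,45000
580,50100,36000
590,14000,26000
600,3200,14680
610,1506,9440
620,942,7550
630,610,5150
640,442,4345
650,368,3750
660,320,3227
670,294,2795
680,278,2407
690,276,2051
700,290,1794
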