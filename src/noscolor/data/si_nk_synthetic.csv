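wavelength_nm,n,k
340,5.1,2.95
350,5.44,2.99
360,6,2.92
370,6.87,2.14
380,6.55,0.92
390,5.98,0.46
400,5.57,0.39
420,5.01,0.24
440,4.75,0.16
460,4.55,0.12
480,4.42,0.09
500,4.3,0.073
520,4.2,0.06
540,4.12,0.048
560,4.05,0.04
580,3.99,0.032
600,3.94,0.025
620,3.9,0.022
640,3.87,0.018
660,3.84,0.015
680,3.81,0.013
700,3.78,0.011
720,3.76,0.009
740,3.73,0.008
760,3.72,0.007
780,3.7,0.006
800,3.69,0.005
830,3.67,0.004
850,3.66,0.004
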