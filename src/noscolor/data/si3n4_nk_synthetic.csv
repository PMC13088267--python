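wavelength_nm,n,k
340,2.1427591,0
345,2.1382135,0
350,2.1338966,0
355,2.1297927,0
360,2.1258874,0
365,2.1221675,0
370,2.1186211,0
375,2.1152369,0
380,2.1120049,0
385,2.1089156,0
390,2.1059605,0
395,2.1031315,0
400,2.1004213,0
405,2.097823,0
410,2.0953303,0
415,2.0929373,0
420,2.0906385,0
425,2.0884288,0
430,2.0863034,0
435,2.084258,0
440,2.0822884,0
445,2.0803907,0
450,2.0785613,0
455,2.0767968,0
460,2.075094,0
465,2.0734499,0
470,2.0718618,0
475,2.0703269,0
480,2.0688429,0
485,2.0674073,0
490,2.0660179,0
495,2.0646728,0
500,2.0633699,0
505,2.0621073,0
510,2.0608834,0
515,2.0596964,0
520,2.0585448,0
525,2.0574271,0
530,2.0563419,0
535,2.0552879,0
540,2.0542638,0
545,2.0532684,0
550,2.0523005,0
555,2.0513591,0
560,2.0504432,0
565,2.0495517,0
570,2.0486837,0
575,2.0478383,0
580,2.0470147,0
585,2.0462121,0
590,2.0454296,0
595,2.0446667,0
600,2.0439224,0
605,2.0431963,0
610,2.0424876,0
615,2.0417957,0
620,2.04112,0
625,2.04046,0
630,2.0398151,0
635,2.0391848,0
640,2.0385687,0
645,2.0379662,0
650,2.0373769,0
655,2.0368003,0
660,2.0362361,0
665,2.0356838,0
670,2.035143,0
675,2.0346135,0
680,2.0340947,0
685,2.0335864,0
690,2.0330883,0
695,2.0326,0
700,2.0321213,0
705,2.0316517,0
710,2.0311912,0
715,2.0307393,0
720,2.0302958,0
725,2.0298605,0
730,2.0294331,0
735,2.0290134,0
740,2.0286012,0
745,2.0281962,0
750,2.0277982,0
755,2.0274071,0
760,2.0270226,0
765,2.0266446,0
770,2.0262728,0
775,2.0259071,0
780,2.0255473,0
785,2.0251933,0
790,2.0248449,0
795,2.0245019,0
800,2.0241641,0
805,2.0238316,0
810,2.023504,0
815,2.0231813,0
820,2.0228633,0
825,2.0225499,0
830,2.0222411,0
835,2.0219365,0
840,2.0216363,0
845,2.0213402,0
850,2.0210481,0
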