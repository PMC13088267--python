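wavelength_nm,value
360,99.72577
361,100.04433
362,100.35836
363,100.66787
364,100.97287
365,101.27337
366,101.56937
367,101.8609
368,102.14796
369,102.43056
370,102.70871
371,102.98243
372,103.25173
373,103.51662
374,103.77713
375,104.03325
376,104.28501
377,104.53243
378,104.77551
379,105.01428
380,105.24875
381,105.47894
382,105.70487
383,105.92655
384,106.14401
385,106.35726
386,106.56631
387,106.7712
388,106.97194
389,107.16855
390,107.36105
391,107.54946
392,107.7338
393,107.91409
394,108.09036
395,108.26262
396,108.4309
397,108.59522
398,108.7556
399,108.91206
400,109.06463
401,109.21334
402,109.35819
403,109.49922
404,109.63645
405,109.76991
406,109.89961
407,110.02558
408,110.14785
409,110.26644
410,110.38137
411,110.49267
412,110.60037
413,110.70448
414,110.80503
415,110.90205
416,110.99557
417,111.0856
418,111.17217
419,111.25532
420,111.33505
421,111.41141
422,111.4844
423,111.55407
424,111.62043
425,111.68352
426,111.74335
427,111.79995
428,111.85334
429,111.90356
430,111.95063
431,111.99458
432,112.03542
433,112.07319
434,112.10791
435,112.1396
436,112.1683
437,112.19402
438,112.2168
439,112.23666
440,112.25362
441,112.26772
442,112.27896
443,112.28739
444,112.29302
445,112.29589
446,112.29601
447,112.29341
448,112.28812
449,112.28016
450,112.26956
451,112.25634
452,112.24053
453,112.22215
454,112.20122
455,112.17778
456,112.15184
457,112.12343
458,112.09257
459,112.0593
460,112.02362
461,111.98557
462,111.94518
463,111.90246
464,111.85743
465,111.81013
466,111.76058
467,111.70879
468,111.6548
469,111.59863
470,111.54029
471,111.47982
472,111.41723
473,111.35255
474,111.2858
475,111.21701
476,111.14619
477,111.07337
478,110.99857
479,110.92182
480,110.84313
481,110.76253
482,110.68004
483,110.59568
484,110.50947
485,110.42144
486,110.3316
487,110.23998
488,110.1466
489,110.05147
490,109.95463
491,109.85608
492,109.75586
493,109.65398
494,109.55045
495,109.44532
496,109.33858
497,109.23026
498,109.12039
499,109.00897
500,108.89604
501,108.78161
502,108.6657
503,108.54832
504,108.42951
505,108.30927
506,108.18762
507,108.06459
508,107.94019
509,107.81444
510,107.68736
511,107.55897
512,107.42928
513,107.29832
514,107.16609
515,107.03262
516,106.89793
517,106.76203
518,106.62494
519,106.48668
520,106.34726
521,106.2067
522,106.06502
523,105.92223
524,105.77835
525,105.63339
526,105.48738
527,105.34033
528,105.19225
529,105.04316
530,104.89307
531,104.74201
532,104.58998
533,104.437
534,104.28309
535,104.12826
536,103.97253
537,103.8159
538,103.6584
539,103.50004
540,103.34084
541,103.1808
542,103.01995
543,102.85829
544,102.69584
545,102.53261
546,102.36862
547,102.20389
548,102.03841
549,101.87221
550,101.70531
551,101.5377
552,101.36942
553,101.20046
554,101.03084
555,100.86058
556,100.68968
557,100.51816
558,100.34603
559,100.17331
560,100
561,99.826116
562,99.651671
563,99.476676
564,99.301142
565,99.12508
566,98.948503
567,98.77142
568,98.593844
569,98.415785
570,98.237254
571,98.058262
572,97.878818
573,97.698935
574,97.518622
575,97.33789
576,97.156748
577,96.975207
578,96.793277
579,96.610967
580,96.428288
581,96.24525
582,96.061861
583,95.878132
584,95.694071
585,95.509689
586,95.324993
587,95.139994
588,94.954701
589,94.769122
590,94.583266
591,94.397142
592,94.210758
593,94.024124
594,93.837247
595,93.650136
596,93.4628
597,93.275246
598,93.087482
599,92.899517
600,92.711358
601,92.523014
602,92.334492
603,92.1458
604,91.956945
605,91.767935
606,91.578777
607,91.389479
608,91.200048
609,91.010491
610,90.820815
611,90.631027
612,90.441135
613,90.251144
614,90.061062
615,89.870896
616,89.680652
617,89.490336
618,89.299956
619,89.109517
620,88.919026
621,88.72849
622,88.537913
623,88.347303
624,88.156665
625,87.966006
626,87.775331
627,87.584647
628,87.393958
629,87.20327
630,87.01259
631,86.821923
632,86.631274
633,86.440648
634,86.250052
635,86.059489
636,85.868967
637,85.678488
638,85.48806
639,85.297686
640,85.107372
641,84.917123
642,84.726943
643,84.536838
644,84.346811
645,84.156868
646,83.967013
647,83.777251
648,83.587587
649,83.398024
650,83.208567
651,83.01922
652,82.829988
653,82.640875
654,82.451885
655,82.263022
656,82.07429
657,81.885693
658,81.697235
659,81.50892
660,81.320751
661,81.132733
662,80.94487
663,80.757164
664,80.56962
665,80.38224
666,80.19503
667,80.007991
668,79.821128
669,79.634444
670,79.447942
671,79.261625
672,79.075497
673,78.889561
674,78.70382
675,78.518278
676,78.332936
677,78.147799
678,77.962869
679,77.778148
680,77.593641
681,77.40935
682,77.225277
683,77.041426
684,76.857799
685,76.674398
686,76.491227
687,76.308288
688,76.125583
689,75.943115
690,75.760887
691,75.578901
692,75.397159
693,75.215663
694,75.034417
695,74.853422
696,74.672681
697,74.492195
698,74.311967
699,74.131999
700,73.952294
701,73.772852
702,73.593677
703,73.41477
704,73.236133
705,73.057769
706,72.879678
707,72.701864
708,72.524327
709,72.34707
710,72.170094
711,71.993401
712,71.816993
713,71.640871
714,71.465038
715,71.289494
716,71.114241
717,70.939282
718,70.764616
719,70.590247
720,70.416175
721,70.242402
722,70.068929
723,69.895758
724,69.722889
725,69.550325
726,69.378067
727,69.206115
728,69.034472
729,68.863138
730,68.692114
731,68.521403
732,68.351004
733,68.180919
734,68.01115
735,67.841696
736,67.67256
737,67.503742
738,67.335244
739,67.167066
740,66.999209
741,66.831674
742,66.664463
743,66.497575
744,66.331013
745,66.164776
746,65.998866
747,65.833283
748,65.668028
749,65.503103
750,65.338507
751,65.174241
752,65.010306
753,64.846704
754,64.683434
755,64.520497
756,64.357893
757,64.195625
758,64.033691
759,63.872092
760,63.71083
761,63.549905
762,63.389316
763,63.229065
764,63.069153
765,62.909579
766,62.750344
767,62.591448
768,62.432893
769,62.274678
770,62.116803
771,61.95927
772,61.802078
773,61.645228
774,61.48872
775,61.332554
776,61.176731
777,61.021251
778,60.866115
779,60.711321
780,60.556872
781,60.402766
782,60.249005
783,60.095588
784,59.942515
785,59.789788
786,59.637405
787,59.485367
788,59.333674
789,59.182326
790,59.031324
791,58.880667
792,58.730355
793,58.580389
794,58.430769
795,58.281494
796,58.132565
797,57.983982
798,57.835745
799,57.687853
800,57.540306
801,57.393106
802,57.246251
803,57.099742
804,56.953578
805,56.807759
806,56.662286
807,56.517158
808,56.372376
809,56.227938
810,56.083846
811,55.940098
812,55.796695
813,55.653636
814,55.510922
815,55.368552
816,55.226525
817,55.084843
818,54.943505
819,54.802509
820,54.661857
821,54.521549
822,54.381582
823,54.241959
824,54.102678
825,53.963738
826,53.825141
827,53.686885
828,53.548971
829,53.411397
830,53.274164
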