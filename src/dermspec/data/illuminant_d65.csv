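wavelength_nm,value
380,90.58270002
381,90.97691109
382,91.36701180
383,91.75298584
384,92.13481767
385,92.51249250
386,92.88599627
387,93.25531566
388,93.62043805
389,93.98135157
390,94.33804504
391,94.69050795
392,95.03873052
393,95.38270363
394,95.72241883
395,96.05786833
396,96.38904500
397,96.71594235
398,97.03855453
399,97.35687631
400,97.67090310
401,97.98063090
402,98.28605632
403,98.58717654
404,98.88398937
405,99.17649315
406,99.46468683
407,99.74856987
408,100.02814232
409,100.30340476
410,100.57435829
411,100.84100456
412,101.10334570
413,101.36138439
414,101.61512378
415,101.86456752
416,102.10971975
417,102.35058507
418,102.58716855
419,102.81947574
420,103.04751262
421,103.27128560
422,103.49080156
423,103.70606778
424,103.91709197
425,104.12388224
426,104.32644712
427,104.52479552
428,104.71893675
429,104.90888049
430,105.09463680
431,105.27621610
432,105.45362919
433,105.62688718
434,105.79600155
435,105.96098412
436,106.12184703
437,106.27860275
438,106.43126404
439,106.57984401
440,106.72435604
441,106.86481381
442,107.00123130
443,107.13362276
444,107.26200271
445,107.38638596
446,107.50678757
447,107.62322284
448,107.73570734
449,107.84425688
450,107.94888750
451,108.04961547
452,108.14645730
453,108.23942969
454,108.32854959
455,108.41383412
456,108.49530063
457,108.57296666
458,108.64684991
459,108.71696832
460,108.78333995
461,108.84598308
462,108.90491614
463,108.96015772
464,109.01172658
465,109.05964161
466,109.10392187
467,109.14458655
468,109.18165500
469,109.21514667
470,109.24508116
471,109.27147820
472,109.29435761
473,109.31373936
474,109.32964350
475,109.34209020
476,109.35109973
477,109.35669247
478,109.35888886
479,109.35770945
480,109.35317488
481,109.34530586
482,109.33412318
483,109.31964770
484,109.30190034
485,109.28090211
486,109.25667405
487,109.22923729
488,109.19861298
489,109.16482234
490,109.12788663
491,109.08782717
492,109.04466530
493,108.99842239
494,108.94911988
495,108.89677919
496,108.84142180
497,108.78306922
498,108.72174295
499,108.65746453
500,108.59025550
501,108.52013744
502,108.44713191
503,108.37126049
504,108.29254475
505,108.21100627
506,108.12666664
507,108.03954743
508,107.94967020
509,107.85705651
510,107.76172791
511,107.66370592
512,107.56301207
513,107.45966785
514,107.35369473
515,107.24511416
516,107.13394757
517,107.02021635
518,106.90394188
519,106.78514549
520,106.66384847
521,106.54007211
522,106.41383762
523,106.28516620
524,106.15407899
525,106.02059710
526,105.88474159
527,105.74653347
528,105.60599370
529,105.46314321
530,105.31800285
531,105.17059345
532,105.02093574
533,104.86905044
534,104.71495818
535,104.55867955
536,104.40023508
537,104.23964523
538,104.07693039
539,103.91211090
540,103.74520704
541,103.57623900
542,103.40522692
543,103.23219086
544,103.05715084
545,102.88012676
546,102.70113848
547,102.52020579
548,102.33734839
549,102.15258591
550,101.96593791
551,101.77742386
552,101.58706316
553,101.39487514
554,101.20087903
555,101.00509401
556,100.80753914
557,100.60823344
558,100.40719580
559,100.20444507
560,100.00000000
561,99.79387925
562,99.58610139
563,99.37668492
564,99.16564825
565,98.95300969
566,98.73878749
567,98.52299977
568,98.30566460
569,98.08679994
570,97.86642367
571,97.64455357
572,97.42120734
573,97.19640259
574,96.97015683
575,96.74248749
576,96.51341188
577,96.28294726
578,96.05111076
579,95.81791945
580,95.58339027
581,95.34754010
582,95.11038571
583,94.87194379
584,94.63223090
585,94.39126356
586,94.14905814
587,93.90563096
588,93.66099823
589,93.41517604
590,93.16818044
591,92.92002732
592,92.67073253
593,92.42031180
594,92.16878076
595,91.91615495
596,91.66244983
597,91.40768074
598,91.15186293
599,90.89501158
600,90.63714174
601,90.37826837
602,90.11840637
603,89.85757050
604,89.59577545
605,89.33303581
606,89.06936606
607,88.80478062
608,88.53929378
609,88.27291974
610,88.00567263
611,87.73756646
612,87.46861516
613,87.19883256
614,86.92823239
615,86.65682829
616,86.38463382
617,86.11166242
618,85.83792746
619,85.56344221
620,85.28821984
621,85.01227342
622,84.73561596
623,84.45826034
624,84.18021937
625,83.90150576
626,83.62213213
627,83.34211101
628,83.06145484
629,82.78017596
630,82.49828662
631,82.21579899
632,81.93272515
633,81.64907707
634,81.36486666
635,81.08010571
636,80.79480595
637,80.50897900
638,80.22263639
639,79.93578958
640,79.64844993
641,79.36062871
642,79.07233711
643,78.78358622
644,78.49438707
645,78.20475058
646,77.91468759
647,77.62420886
648,77.33332504
649,77.04204674
650,76.75038444
651,76.45834856
652,76.16594944
653,75.87319733
654,75.58010238
655,75.28667468
656,74.99292422
657,74.69886093
658,74.40449465
659,74.10983511
660,73.81489200
661,73.51967491
662,73.22419335
663,72.92845675
664,72.63247446
665,72.33625575
666,72.03980983
667,71.74314580
668,71.44627270
669,71.14919950
670,70.85193506
671,70.55448821
672,70.25686767
673,69.95908209
674,69.66114005
675,69.36305005
676,69.06482051
677,68.76645980
678,68.46797619
679,68.16937788
680,67.87067300
681,67.57186962
682,67.27297571
683,66.97399920
684,66.67494792
685,66.37582964
686,66.07665207
687,65.77742283
688,65.47814948
689,65.17883951
690,64.87950035
691,64.58013933
692,64.28076374
693,63.98138080
694,63.68199766
695,63.38262138
696,63.08325899
697,62.78391743
698,62.48460357
699,62.18532424
700,61.88608617
701,61.58689606
702,61.28776052
703,60.98868610
704,60.68967930
705,60.39074654
706,60.09189419
707,59.79312855
708,59.49445585
709,59.19588228
710,58.89741395
711,58.59905692
712,58.30081717
713,58.00270065
714,57.70471324
715,57.40686073
716,57.10914890
717,56.81158343
718,56.51416997
719,56.21691410
720,55.91982133
721,55.62289714
722,55.32614694
723,55.02957608
724,54.73318985
725,54.43699350
726,54.14099221
727,53.84519112
728,53.54959530
729,53.25420977
730,52.95903951
731,52.66408942
732,52.36936437
733,52.07486917
734,51.78060858
735,51.48658730
736,51.19280999
737,50.89928125
738,50.60600563
739,50.31298763
740,50.02023170
741,49.72774225
742,49.43552362
743,49.14358013
744,48.85191602
745,48.56053550
746,48.26944272
747,47.97864181
748,47.68813682
749,47.39793176
750,47.10803061
751,46.81843729
752,46.52915568
753,46.24018961
754,45.95154286
755,45.66321917
756,45.37522225
757,45.08755575
758,44.80022326
759,44.51322837
760,44.22657459
761,43.94026540
762,43.65430423
763,43.36869449
764,43.08343951
765,42.79854262
766,42.51400708
767,42.22983612
768,41.94603292
769,41.66260064
770,41.37954237
771,41.09686120
772,40.81456013
773,40.53264218
774,40.25111027
775,39.96996733
776,39.68921622
777,39.40885979
778,39.12890082
779,38.84934209
780,38.57018630
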