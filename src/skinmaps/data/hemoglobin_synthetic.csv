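wavelength_nm,mu_a_oxy_cm1,mu_a_deoxy_cm1
400,1424.39,1194.13
402,1655.54,1252.76
404,1890.39,1317.48
406,2119.5,1388.75
408,2332.07,1467.05
410,2516.78,1552.91
412,2691.55,1649.14
414,2784.52,1757.63
416,2647.87,1877.18
418,2348.4,2006.08
420,2034.84,2141.94
422,1709.89,2308.92
424,1363.06,2515.26
426,1056.29,2726.11
428,815.423,2893.99
430,642.582,2962.5
432,509.984,2821.88
434,400.968,2482.25
436,318.607,2070.5
438,261.013,1681.61
440,224.904,1365.49
442,202.228,1069.56
444,185.123,788.286
446,171.612,570.63
448,160.25,423.501
450,149.936,336.37
452,140.044,282.709
454,130.939,241.868
456,123.084,210.991
458,116.826,187.987
460,112.452,171.355
462,109.508,158.743
464,107.187,148.365
466,105.258,139.983
468,103.509,133.412
470,101.742,128.516
472,99.7166,124.695
474,97.5624,121.426
476,95.6297,118.727
478,94.2421,116.619
480,93.7099,115.129
482,94.023,113.989
484,94.863,112.965
486,96.0835,112.137
488,97.5359,111.583
490,99.0647,111.381
492,100.815,111.429
494,103.015,111.568
496,105.625,111.789
498,108.607,112.087
500,111.916,112.452
502,115.899,113.555
504,120.783,115.824
506,126.324,118.893
508,132.231,122.374
510,138.155,125.839
512,144.081,129.288
514,150.26,133.079
516,156.69,137.283
518,163.367,141.979
520,170.284,147.258
522,177.302,153.432
524,184.418,160.671
526,191.863,168.856
528,199.9,177.836
530,208.839,187.42
532,220.572,198.611
534,235.733,211.871
536,252.469,225.928
538,268.35,239.138
540,280.342,249.493
542,285.071,257.368
544,280.321,264.507
546,268.788,270.751
548,254.5,275.943
550,240.968,279.93
552,225.635,283.269
554,207.492,285.647
556,190.941,285.983
558,179.167,285.76
560,174.675,285.371
562,179,281.853
564,190.238,273.63
566,205.791,262.859
568,222.386,251.53
570,235.613,241.354
572,246.145,232.212
574,256.717,222.911
576,264.969,213.358
578,268.299,203.484
580,250.958,193.319
582,212.793,182.791
584,172.508,171.746
586,138.434,159.923
588,104.246,146.882
590,77.1098,133.871
592,56.602,120.693
594,40.6171,107.51
596,29.2687,95.6292
598,21.756,85.8425
600,17.1355,78.5931
602,14.1929,73.2919
604,12.0224,68.9268
606,10.3775,65.217
608,9.09514,61.9373
610,8.0644,58.9033
612,7.23602,56.1873
614,6.5688,53.825
616,6.00664,51.6285
618,5.50853,49.4387
620,5.04427,47.1227
622,4.59901,44.605
624,4.18675,41.9936
626,3.82195,39.4291
628,3.51346,37.0228
630,3.26646,34.8601
632,3.06289,32.8646
634,2.88067,30.9362
636,2.71753,29.1026
638,2.57147,27.3845
640,2.44076,25.7971
642,2.32388,24.351
644,2.2195,23.0529
646,2.12647,21.907
648,2.04379,20.9157
650,1.97058,20.0807
652,1.90537,19.3906
654,1.84713,18.8033
656,1.79579,18.2788
658,1.75127,17.7817
660,1.71355,17.2801
662,1.679,16.7755
664,1.64468,16.2879
666,1.61151,15.8163
668,1.58036,15.3598
670,1.55204,14.9173
672,1.52728,14.4881
674,1.50679,14.0713
676,1.49126,13.6664
678,1.4814,13.2725
680,1.47794,12.8891
682,1.47891,12.5124
684,1.48171,12.1408
686,1.48619,11.777
688,1.49222,11.4232
690,1.49965,11.0815
692,1.50834,10.7536
694,1.51815,10.4409
696,1.52895,10.1448
698,1.54058,9.86639
700,1.55291,9.6066
702,1.57011,9.36309
704,1.59568,9.13206
706,1.62848,8.91229
708,1.66735,8.70264
710,1.71105,8.50207
712,1.75823,8.30961
714,1.8074,8.12436
716,1.85689,7.94549
718,1.90483,7.77224
720,1.94917,7.60389
722,1.99047,7.4178
724,2.03102,7.21666
726,2.07124,7.0351
728,2.1116,6.90442
730,2.15261,6.85421
732,2.19482,6.8742
734,2.23883,6.92786
736,2.28527,7.00588
738,2.33483,7.09883
740,2.38826,7.19692
742,2.44746,7.31706
744,2.51322,7.4745
746,2.58462,7.656
748,2.66065,7.8472
750,2.74015,8.03227
752,2.8218,8.23945
754,2.90415,8.48168
756,2.98553,8.71569
758,3.06412,8.89347
760,3.13794,8.96402
762,3.20832,8.88471
764,3.27795,8.66815
766,3.34678,8.34923
768,3.41474,7.96336
770,3.4818,7.54345
772,3.54789,7.11803
774,3.61299,6.71059
776,3.67705,6.33965
778,3.74005,6.01959
780,3.80194,5.76182
782,3.8626,5.53748
784,3.92197,5.31496
786,3.98019,5.09944
788,4.0374,4.89531
790,4.09378,4.70624
792,4.14948,4.53529
794,4.20471,4.38503
796,4.25965,4.25773
798,4.31453,4.15548
800,4.36956,4.08039
802,4.42432,4.02089
804,4.47833,3.96441
806,4.53176,3.91175
808,4.58478,3.86367
810,4.63757,3.82088
812,4.69032,3.78409
814,4.74322,3.75399
816,4.7965,3.73127
818,4.85036,3.71666
820,4.90504,3.71091
822,4.96144,3.70991
824,5.01988,3.709
826,5.07968,3.7082
828,5.14013,3.70751
830,5.20049,3.70691
832,5.25999,3.70643
834,5.31781,3.70605
836,5.37312,3.70577
838,5.42503,3.70561
840,5.47266,3.70556
842,5.51661,3.70617
844,5.5583,3.70791
846,5.59803,3.71068
848,5.63608,3.71434
850,5.67277,3.71878
852,5.70843,3.72387
854,5.74339,3.7295
856,5.77798,3.73555
858,5.81257,3.74189
860,5.8475,3.74839
862,5.88283,3.75615
864,5.91824,3.76611
866,5.95354,3.77796
868,5.98851,3.7914
870,6.02296,3.80612
872,6.05665,3.82179
874,6.08938,3.83811
876,6.12091,3.85474
878,6.15103,3.87135
880,6.1795,3.88762
882,6.207,3.90573
884,6.23423,3.92731
886,6.26097,3.95116
888,6.28698,3.97605
890,6.31206,4.00073
892,6.33596,4.02391
894,6.35845,4.04427
896,6.3793,4.06047
898,6.39826,4.07118
900,6.41511,4.07504
902,6.43112,4.07428
904,6.44744,4.07208
906,6.4636,4.06854
908,6.47914,4.06379
910,6.49359,4.05794
912,6.50648,4.05109
914,6.51733,4.04338
916,6.52568,4.0349
918,6.53103,4.02579
920,6.53292,4.01614
922,6.53242,4.00183
924,6.53101,3.97974
926,6.52881,3.95148
928,6.52592,3.91866
930,6.52247,3.88286
932,6.51857,3.8456
934,6.51434,3.80838
936,6.50988,3.77262
938,6.50533,3.73968
940,6.50079,3.71091
942,6.49604,3.68448
944,6.49079,3.65795
946,6.48499,3.63164
948,6.47859,3.6059
950,6.47157,3.58104
952,6.46389,3.55738
954,6.45551,3.53521
956,6.4464,3.51484
958,6.43651,3.49656
960,6.42582,3.48065
962,6.41332,3.46645
964,6.39821,3.45309
966,6.38072,3.44054
968,6.36109,3.42877
970,6.33956,3.41777
972,6.31637,3.40751
974,6.29174,3.39798
976,6.26593,3.38916
978,6.23914,3.38102
980,6.21162,3.37355
982,6.18228,3.36652
984,6.15003,3.35973
986,6.11511,3.35324
988,6.07776,3.34709
990,6.03821,3.34133
992,5.99668,3.336
994,5.95341,3.33116
996,5.90863,3.32685
998,5.86254,3.32311
1000,5.81537,3.32001
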