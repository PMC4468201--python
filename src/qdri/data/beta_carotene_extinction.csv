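wavelength_nm,extinction_1_per_M_cm
420,85000.0
421,87620.3
422,90020.9
423,92111.4
424,93801.2
425,95000.0
426,95768.4
427,96317.4
428,96782.3
429,97298.1
430,98000.0
431,98974.4
432,100195.2
433,101628.8
434,103241.6
435,105000.0
436,107085.4
437,109592.2
438,112356.3
439,115213.6
440,118000.0
441,120869.1
442,123931.7
443,126959.7
444,129725.2
445,132000.0
446,134030.2
447,136046.5
448,137797.7
449,139032.6
450,139500.0
451,139111.7
452,138115.0
453,136762.4
454,135306.6
455,134000.0
456,132848.2
457,131681.9
458,130491.5
459,129267.4
460,128000.0
461,126579.3
462,125008.7
463,123448.5
464,122058.8
465,121000.0
466,120150.4
467,119339.2
468,118652.8
469,118177.6
470,118000.0
471,118218.8
472,118750.0
473,119406.2
474,120000.0
475,120593.8
476,121250.0
477,121781.2
478,122000.0
479,121549.6
480,120382.4
481,118773.9
482,117000.0
483,114791.8
484,111876.3
485,108522.6
486,105000.0
487,101098.4
488,96696.4
489,92196.2
490,88000.0
491,84259.1
492,80749.5
493,77310.4
494,73780.8
495,70000.0
496,65811.2
497,61305.6
498,56694.4
499,52188.8
500,48000.0
501,44076.7
502,40262.1
503,36609.1
504,33170.8
505,30000.0
506,27032.6
507,24200.9
508,21553.0
509,19136.7
510,17000.0
511,15076.5
512,13286.5
513,11658.3
514,10220.1
515,9000.0
516,7953.3
517,7013.8
518,6177.6
519,5441.0
520,4800.0
521,4230.8
522,3713.8
523,3251.4
524,2846.0
525,2500.0
526,2193.7
527,1911.5
528,1662.5
529,1455.6
530,1300.0
531,1178.6
532,1068.1
533,967.9
534,877.3
535,795.7
536,722.5
537,656.9
538,598.4
539,546.3
540,500.0
541,457.6
542,417.7
543,380.5
544,346.0
545,314.2
546,285.3
547,259.4
548,236.4
549,216.6
550,200.0
551,185.5
552,172.0
553,159.4
554,147.9
555,137.4
556,127.9
557,119.4
558,111.9
559,105.4
560,100.0
561,95.2
562,90.6
563,86.3
564,82.2
565,78.2
566,74.5
567,71.0
568,67.6
569,64.5
570,61.5
571,58.7
572,56.0
573,53.5
574,51.2
575,49.0
576,46.9
577,45.0
578,43.2
579,41.6
580,40.0
581,38.5
582,37.1
583,35.7
584,34.4
585,33.1
586,31.9
587,30.7
588,29.6
589,28.5
590,27.5
591,26.5
592,25.6
593,24.7
594,23.9
595,23.1
596,22.4
597,21.7
598,21.1
599,20.5
600,20.0
601,19.5
602,19.0
603,18.5
604,18.1
605,17.6
606,17.2
607,16.7
608,16.3
609,15.9
610,15.5
611,15.1
612,14.7
613,14.3
614,13.9
615,13.6
616,13.2
617,12.8
618,12.5
619,12.2
620,11.8
621,11.5
622,11.2
623,10.9
624,10.6
625,10.3
626,10.0
627,9.8
628,9.5
629,9.2
630,9.0
631,8.7
632,8.5
633,8.2
634,8.0
635,7.8
636,7.5
637,7.3
638,7.1
639,6.9
640,6.7
641,6.5
642,6.3
643,6.2
644,6.0
645,5.8
646,5.6
647,5.5
648,5.3
649,5.2
650,5.0
651,4.9
652,4.7
653,4.6
654,4.4
655,4.3
656,4.1
657,4.0
658,3.8
659,3.7
660,3.5
661,3.4
662,3.2
663,3.1
664,3.0
665,2.8
666,2.7
667,2.5
668,2.4
669,2.3
670,2.2
671,2.0
672,1.9
673,1.8
674,1.7
675,1.6
676,1.5
677,1.3
678,1.2
679,1.1
680,1.0
681,0.9
682,0.9
683,0.8
684,0.7
685,0.6
686,0.5
687,0.5
688,0.4
689,0.3
690,0.3
691,0.2
692,0.2
693,0.1
694,0.1
695,0.1
696,0.0
697,0.0
698,0.0
699,0.0
700,0.0
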