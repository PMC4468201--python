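wavelength_nm,extinction_1_per_M_cm
420,266000.0
421,247493.7
422,229601.2
423,212361.8
424,195815.0
425,180000.0
426,164185.0
427,148278.2
428,133278.8
429,120186.3
430,110000.0
431,102272.0
432,95696.0
433,89984.0
434,84848.0
435,80000.0
436,74848.0
437,69504.0
438,64736.0
439,61312.0
440,60000.0
441,60025.7
442,60097.0
443,60205.6
444,60342.7
445,60500.0
446,60846.1
447,61433.7
448,62079.7
449,62601.5
450,62816.0
451,62192.1
452,60591.6
453,58421.5
454,56088.6
455,54000.0
456,52071.3
457,50030.3
458,48001.6
459,46109.9
460,44480.0
461,43053.7
462,41690.5
463,40391.7
464,39158.6
465,37992.4
466,36894.4
467,35865.8
468,34907.9
469,34021.8
470,33209.0
471,32457.3
472,31751.3
473,31087.3
474,30461.4
475,29869.8
476,29308.8
477,28774.5
478,28263.1
479,27770.9
480,27294.0
481,26830.7
482,26382.0
483,25948.7
484,25531.1
485,25129.8
486,24745.5
487,24378.6
488,24029.7
489,23699.3
490,23388.0
491,23086.8
492,22788.6
493,22497.0
494,22215.4
495,21947.3
496,21696.2
497,21465.7
498,21259.1
499,21080.1
500,20932.0
501,20800.4
502,20670.5
503,20545.1
504,20427.0
505,20319.2
506,20224.6
507,20146.0
508,20086.2
509,20048.3
510,20035.0
511,20095.5
512,20269.4
513,20545.1
514,20911.1
515,21355.8
516,21867.7
517,22435.2
518,23046.8
519,23690.9
520,24356.0
521,25197.0
522,26338.5
523,27723.5
524,29294.7
525,30995.1
526,32767.7
527,34555.2
528,36300.7
529,37947.0
530,39437.0
531,40790.7
532,42089.3
533,43367.2
534,44659.3
535,46000.0
536,47544.3
537,49270.4
538,50947.9
539,52346.6
540,53236.0
541,53757.5
542,54000.0
543,53840.9
544,53409.0
545,52772.6
546,52000.0
547,50462.8
548,47970.1
549,45246.4
550,43016.0
551,41317.5
552,39730.6
553,38291.3
554,37035.7
555,36000.0
556,35063.0
557,34149.9
558,33366.6
559,32819.1
560,32613.0
561,32739.2
562,33087.0
563,33610.4
564,34263.4
565,35000.0
566,36136.7
567,37874.5
568,39993.4
569,42273.8
570,44496.0
571,47173.4
572,50307.9
573,52912.5
574,54000.0
575,53848.2
576,53428.6
577,52794.6
578,52000.0
579,50267.9
580,47238.1
581,43589.3
582,40000.0
583,36354.5
584,32362.0
585,28438.5
586,25000.0
587,22016.8
588,19242.0
589,16765.5
590,14677.0
591,12909.4
592,11324.6
593,9905.8
594,8636.5
595,7500.0
596,6413.4
597,5358.8
598,4417.5
599,3670.8
600,3200.0
601,2912.5
602,2659.4
603,2437.8
604,2244.5
605,2076.5
606,1930.5
607,1803.6
608,1692.6
609,1594.5
610,1506.0
611,1425.4
612,1352.4
613,1286.1
614,1225.7
615,1170.5
616,1119.5
617,1072.0
618,1027.1
619,984.0
620,942.0
621,900.9
622,861.1
623,822.9
624,786.4
625,751.6
626,718.9
627,688.2
628,659.7
629,633.6
630,610.0
631,588.1
632,567.3
633,547.4
634,528.6
635,511.0
636,494.5
637,479.3
638,465.5
639,453.0
640,442.0
641,432.1
642,423.0
643,414.6
644,406.8
645,399.5
646,392.7
647,386.2
648,380.0
649,373.9
650,368.0
651,362.1
652,356.1
653,350.2
654,344.5
655,339.1
656,334.0
657,329.4
658,325.3
659,321.8
660,319.0
661,316.6
662,314.3
663,312.1
664,309.9
665,307.8
666,305.7
667,303.8
668,301.9
669,300.2
670,298.5
671,297.0
672,295.6
673,294.4
674,293.3
675,292.3
676,291.5
677,290.9
678,290.4
679,290.1
680,290.0
681,290.0
682,290.0
683,290.0
684,290.0
685,290.0
686,290.0
687,290.0
688,290.0
689,290.0
690,290.0
691,290.0
692,290.0
693,290.0
694,290.0
695,290.0
696,290.0
697,290.0
698,290.0
699,290.0
700,290.0
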