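group_id,label,sex,geography,period,person_years,rate,ci_low,ci_high
221,Health professionals,male,EW,2001,12873,225,145,304
24,Business and public service professionals,male,EW,2001,41276,228,182,274
113,Functional managers,male,EW,2001,61089,233,194,273
115,Financial institution and office managers,male,EW,2001,21375,234,170,299
11,Corporate managers and directors,male,EW,2001,13934,250,175,326
231,Teaching professionals,male,EW,2001,36736,262,210,313
112,Production managers,male,EW,2001,55718,265,219,311
331,Protective service occupations,male,EW,2001,28834,265,190,340
213,Information and communication technology professionals,male,EW,2001,31489,267,187,348
353,Business and finance associate professionals,male,EW,2001,25992,269,198,339
311,Science and engineering technicians,male,EW,2001,23177,270,199,341
116,"Managers in distribution, storage, and retailing",male,EW,2001,44677,277,226,327
212,Engineering professionals,male,EW,2001,35715,282,226,338
312,Draughts persons and building inspectors,male,EW,2001,5009,282,137,428
321,Health associate professionals,male,EW,2001,9248,288,171,404
351,Transport associate professionals,male,EW,2001,5078,290,117,464
356,Public service and other associate professionals,male,EW,2001,13681,309,212,405
117,Protective service officers,male,EW,2001,6365,323,188,459
123,Managers and proprietors in other service industries,male,EW,2001,36544,333,278,387
524,Electrical trades,male,EW,2001,41849,333,276,389
323,Social welfare associate professionals,male,EW,2001,5084,334,166,501
621,Leisure and travel service occupations,male,EW,2001,6145,345,165,524
412,Administrative occupations: finance,male,EW,2001,23118,347,265,429
421,Secretarial and related occupations,male,EW,2001,4784,348,187,510
34,"Culture, media, and sports occupations",male,EW,2001,32202,350,273,428
313,Information technology service delivery occupations,male,EW,2001,10582,350,169,532
354,Sales and related associate professionals,male,EW,2001,26967,362,285,438
712,Sales-related occupations,male,EW,2001,9552,368,251,485
411,Administrative occupations: government and related organisations,male,EW,2001,11250,373,268,479
721,Customer service occupations,male,EW,2001,8397,385,198,573
921,Elementary administration occupations,male,EW,2001,22354,389,305,473
549,Skilled trades not elsewhere classified,male,EW,2001,9553,391,259,524
522,"Metal machining, fitting, and instrument making trades",male,EW,2001,42963,400,342,458
511,Agricultural trades,male,EW,2001,23913,402,325,479
542,Printing trades,male,EW,2001,7140,403,244,562
611,Health care and related personal services,male,EW,2001,11400,413,287,539
413,Administrative occupations: records,male,EW,2001,20129,418,318,517
531,Construction trades,male,EW,2001,71558,419,370,467
812,Plant and machine operatives,male,EW,2001,38091,423,360,487
711,Sales assistants and retail cashiers,male,EW,2001,33239,429,331,526
543,Food preparation trades,male,EW,2001,23061,439,335,542
821,Transport drivers and operatives,male,EW,2001,82677,445,401,489
532,Building trades,male,EW,2001,23344,446,360,532
12,Managers and proprietors in agriculture and services,male,EW,2001,23348,450,364,536
523,Vehicle trades,male,EW,2001,23097,456,358,553
415,Administrative occupations: general,male,EW,2001,16102,461,342,581
622,Hairdressers and related occupations,male,EW,2001,2755,492,226,759
813,Assemblers and routine operatives,male,EW,2001,25176,501,410,593
814,Construction operatives,male,EW,2001,16247,505,399,611
811,Process operatives,male,EW,2001,30195,529,445,614
914,Elementary goods storage occupations,male,EW,2001,37887,539,459,619
924,Elementary security occupations,male,EW,2001,15272,544,433,655
822,Mobile machine drivers and operatives,male,EW,2001,14661,556,435,676
925,Elementary sales occupations,male,EW,2001,3571,556,209,903
521,"Metal forming, welding, and related trades",male,EW,2001,16479,563,451,675
623,Housekeeping occupations,male,EW,2001,5202,567,402,723
541,Textiles and garments trades,male,EW,2001,3809,569,330,808
923,Elementary cleaning occupations,male,EW,2001,20096,592,487,696
414,Administrative occupations: communications,male,EW,2001,2204,604,246,962
911,Elementary agricultural occupations,male,EW,2001,8101,623,441,805
922,Elementary personal services occupations,male,EW,2001,21359,650,510,790
913,Elementary process plant occupations,male,EW,2001,32513,672,576,767
912,Elementary construction occupations,male,EW,2001,22988,701,593,809
none,No occupation reported,male,EW,2001,39614,1189,1014,1364
all,All those reporting an occupation,male,EW,2001,1457772,384,374,394
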