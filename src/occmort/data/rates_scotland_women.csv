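group_id,label,sex,geography,period,person_years,rate,ci_low,ci_high
11,Corporate managers and directors,female,SCO,1991,,194,122,267
11,Corporate managers and directors,female,SCO,2001,,178,131,225
12,Managers and proprietors in agriculture and services,female,SCO,1991,,386,243,529
12,Managers and proprietors in agriculture and services,female,SCO,2001,,236,147,325
123,Managers and proprietors in other service industries,female,SCO,1991,,304,178,429
123,Managers and proprietors in other service industries,female,SCO,2001,,243,148,338
21,"Science, research, engineering, and technology professionals",female,SCO,2001,,429,24,833
221,Health professionals,female,SCO,1991,,259,16,502
221,Health professionals,female,SCO,2001,,215,63,366
231,Teaching professionals,female,SCO,1991,,220,164,276
231,Teaching professionals,female,SCO,2001,,160,122,197
24,Business and public service professionals,female,SCO,1991,,221,80,361
24,Business and public service professionals,female,SCO,2001,,201,109,292
31,Science and technology associate professionals,female,SCO,1991,,332,166,548
31,Science and technology associate professionals,female,SCO,2001,,220,104,341
321,Health associate professionals,female,SCO,1991,,242,177,307
321,Health associate professionals,female,SCO,2001,,241,186,296
322,Therapists,female,SCO,2001,,148,28,269
323,Social welfare associate professionals,female,SCO,1991,,356,169,544
323,Social welfare associate professionals,female,SCO,2001,,202,110,295
331,Protective service occupations,female,SCO,2001,,570,42,1097
34,"Culture, media, and sports occupations",female,SCO,1991,,340,32,647
34,"Culture, media, and sports occupations",female,SCO,2001,,203,83,323
35,Business and public service associate professionals,female,SCO,1991,,278,151,406
35,Business and public service associate professionals,female,SCO,2001,,200,131,269
411,Administrative occupations: government and related organisations,female,SCO,1991,,222,141,303
411,Administrative occupations: government and related organisations,female,SCO,2001,,238,154,321
412,Administrative occupations: finance,female,SCO,1991,,212,149,274
412,Administrative occupations: finance,female,SCO,2001,,249,190,308
413,Administrative occupations: records,female,SCO,1991,,210,128,292
413,Administrative occupations: records,female,SCO,2001,,222,147,297
414,Administrative occupations: communications,female,SCO,1991,,314,125,502
414,Administrative occupations: communications,female,SCO,2001,,273,118,428
415,Administrative occupations: general,female,SCO,1991,,246,175,318
415,Administrative occupations: general,female,SCO,2001,,226,177,276
421,Secretarial and related occupations,female,SCO,1991,,206,160,253
421,Secretarial and related occupations,female,SCO,2001,,223,180,266
511,Agricultural trades,female,SCO,2001,,118,15,221
52,Skilled metal and electrical trades,female,SCO,2001,,387,80,694
541,Textiles and garments trades,female,SCO,1991,,406,142,669
541,Textiles and garments trades,female,SCO,2001,,478,200,756
542,Printing trades,female,SCO,1991,,756,157,1356
542,Printing trades,female,SCO,2001,,330,38,622
543,Food preparation trades,female,SCO,1991,,301,195,407
543,Food preparation trades,female,SCO,2001,,422,299,546
611,Health care and related personal services,female,SCO,1991,,288,221,354
611,Health care and related personal services,female,SCO,2001,,284,237,330
612,Child care and related personal services,female,SCO,1991,,199,96,301
612,Child care and related personal services,female,SCO,2001,,232,156,309
621,Leisure and travel service occupations,female,SCO,1991,,258,36,480
621,Leisure and travel service occupations,female,SCO,2001,,228,99,357
622,Hairdressers and related occupations,female,SCO,2001,,356,185,526
623,Housekeeping occupations,female,SCO,1991,,323,141,506
623,Housekeeping occupations,female,SCO,2001,,254,129,380
711,Sales assistants and retail cashiers,female,SCO,1991,,279,231,327
711,Sales assistants and retail cashiers,female,SCO,2001,,308,264,351
712,Sales-related occupations,female,SCO,1991,,372,137,608
712,Sales-related occupations,female,SCO,2001,,186,46,325
721,Customer service occupations,female,SCO,2001,,158,83,233
811,Process operatives,female,SCO,1991,,331,194,467
811,Process operatives,female,SCO,2001,,338,218,457
812,Plant and machine operatives,female,SCO,1991,,481,141,822
812,Plant and machine operatives,female,SCO,2001,,663,320,1006
813,Assemblers and routine operatives,female,SCO,1991,,286,207,365
813,Assemblers and routine operatives,female,SCO,2001,,494,399,588
821,Transport drivers and operatives,female,SCO,1991,,436,112,760
821,Transport drivers and operatives,female,SCO,2001,,257,52,462
911,Elementary agricultural occupations,female,SCO,1991,,425,50,801
913,Elementary process plant occupations,female,SCO,1991,,363,230,497
913,Elementary process plant occupations,female,SCO,2001,,467,338,565
914,Elementary goods storage occupations,female,SCO,1991,,521,195,848
914,Elementary goods storage occupations,female,SCO,2001,,528,189,867
921,Elementary administration occupations,female,SCO,1991,,314,61,567
921,Elementary administration occupations,female,SCO,2001,,354,180,528
922,Elementary personal services occupations,female,SCO,1991,,307,239,375
922,Elementary personal services occupations,female,SCO,2001,,346,276,415
923,Elementary cleaning occupations,female,SCO,1991,,337,292,382
923,Elementary cleaning occupations,female,SCO,2001,,426,371,481
924,Elementary security occupations,female,SCO,1991,,146,26,265
924,Elementary security occupations,female,SCO,2001,,339,178,500
none,No occupation reported,female,SCO,1991,,597,557,636
none,No occupation reported,female,SCO,2001,,695,628,762
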