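group_id,label,sex,geography,period,person_years,rate,ci_low,ci_high
34,"Culture, media, and sports occupations",female,EW,2001,26903,133,78,188
24,Business and public service professionals,female,EW,2001,25728,159,104,214
231,Teaching professionals,female,EW,2001,79871,180,152,208
21,"Science, research, engineering, and technology professionals",female,EW,2001,13446,180,82,279
35,Business and public service associate professionals,female,EW,2001,64710,188,146,230
31,Science and technology associate professionals,female,EW,2001,15796,203,127,279
612,Child care and related personal services,female,EW,2001,55829,204,157,250
11,Corporate managers and directors,female,EW,2001,106025,209,178,239
622,Hairdressers and related occupations,female,EW,2001,21910,209,142,277
221,Health professionals,female,EW,2001,10099,213,107,318
543,Food preparation trades,female,EW,2001,18319,217,153,281
421,Secretarial and related occupations,female,EW,2001,112533,218,192,244
925,Elementary sales occupations,female,EW,2001,6775,218,93,344
914,Elementary goods storage occupations,female,EW,2001,7984,220,104,336
621,Leisure and travel service occupations,female,EW,2001,12344,222,116,328
123,Managers and proprietors in other service industries,female,EW,2001,23180,227,162,291
721,Customer service occupations,female,EW,2001,25489,230,153,307
321,Health associate professionals,female,EW,2001,58260,230,191,270
415,Administrative occupations: general,female,EW,2001,76601,233,198,268
323,Social welfare associate professionals,female,EW,2001,13795,236,153,318
511,Agricultural trades,female,EW,2001,4776,251,114,389
542,Printing trades,female,EW,2001,3557,256,104,409
411,Administrative occupations: government and related organisations,female,EW,2001,21080,263,192,334
412,Administrative occupations: finance,female,EW,2001,72532,264,223,305
712,Sales-related occupations,female,EW,2001,9852,265,156,375
821,Transport drivers and operatives,female,EW,2001,6560,279,132,426
611,Health care and related personal services,female,EW,2001,88120,290,255,325
924,Elementary security occupations,female,EW,2001,16424,301,222,380
711,Sales assistants and retail cashiers,female,EW,2001,137985,305,275,336
623,Housekeeping occupations,female,EW,2001,8417,306,204,407
922,Elementary personal services occupations,female,EW,2001,59492,314,265,363
413,Administrative occupations: records,female,EW,2001,37807,333,271,394
811,Process operatives,female,EW,2001,17107,346,259,433
923,Elementary cleaning occupations,female,EW,2001,65159,352,311,394
52,Skilled metal and electrical trades,female,EW,2001,4745,367,184,550
414,Administrative occupations: communications,female,EW,2001,6727,368,233,502
549,Skilled trades not elsewhere classified,female,EW,2001,4170,380,175,585
921,Elementary administration occupations,female,EW,2001,12940,383,275,492
813,Assemblers and routine operatives,female,EW,2001,34561,386,324,448
12,Managers and proprietors in agriculture and services,female,EW,2001,23892,397,318,476
913,Elementary process plant occupations,female,EW,2001,30212,405,334,476
541,Textiles and garments trades,female,EW,2001,3810,483,266,700
812,Plant and machine operatives,female,EW,2001,8707,517,370,663
none,No occupation reported,female,EW,2001,83370,587,523,651
all,All those reporting an occupation,female,EW,2001,1485036,263,255,272
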