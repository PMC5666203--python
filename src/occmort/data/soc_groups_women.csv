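group_id,sex,label,member_codes,includes_no_occupation
11,female,Corporate managers and directors,11,0
12,female,Managers and proprietors in agriculture and services,12,0
123,female,Managers and proprietors in other service industries,123,0
21,female,"Science, research, engineering, and technology professionals",21,0
221,female,Health professionals,221,0
231,female,Teaching professionals,231,0
24,female,Business and public service professionals,24,0
31,female,Science and technology associate professionals,31,0
321,female,Health associate professionals,321,0
322,female,Therapists,322,0
323,female,Social welfare associate professionals,323,0
331,female,Protective service occupations,331,0
34,female,"Culture, media, and sports occupations",34,0
35,female,Business and public service associate professionals,35,0
411,female,Administrative occupations: government and related organisations,411,0
412,female,Administrative occupations: finance,412,0
413,female,Administrative occupations: records,413,0
414,female,Administrative occupations: communications,414,0
415,female,Administrative occupations: general,415,0
421,female,Secretarial and related occupations,421,0
511,female,Agricultural trades,511,0
52,female,Skilled metal and electrical trades,52,0
541,female,Textiles and garments trades,541,0
542,female,Printing trades,542,0
543,female,Food preparation trades,543,0
549,female,Skilled trades not elsewhere classified,549,0
611,female,Health care and related personal services,611,0
612,female,Child care and related personal services,612,0
621,female,Leisure and travel service occupations,621,0
622,female,Hairdressers and related occupations,622,0
623,female,Housekeeping occupations,623,0
711,female,Sales assistants and retail cashiers,711,0
712,female,Sales-related occupations,712,0
721,female,Customer service occupations,721,0
811,female,Process operatives,811,0
812,female,Plant and machine operatives,812,0
813,female,Assemblers and routine operatives,813,0
821,female,Transport drivers and operatives,821,0
911,female,Elementary agricultural occupations,911,0
913,female,Elementary process plant occupations,913,0
914,female,Elementary goods storage occupations,914,0
921,female,Elementary administration occupations,921,0
922,female,Elementary personal services occupations,922,0
923,female,Elementary cleaning occupations,923,0
924,female,Elementary security occupations,924,0
925,female,Elementary sales occupations,925,0
none,female,No occupation reported,,1
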