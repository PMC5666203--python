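group_id,sex,label,member_codes,includes_no_occupation
11,male,Corporate managers and directors,11,0
112,male,Production managers,112,0
113,male,Functional managers,113,0
115,male,Financial institution and office managers,115,0
116,male,"Managers in distribution, storage, and retailing",116,0
117,male,Protective service officers,117,0
12,male,Managers and proprietors in agriculture and services,12,0
123,male,Managers and proprietors in other service industries,123,0
211,male,Natural and social science professionals,211,0
212,male,Engineering professionals,212,0
213,male,Information and communication technology professionals,213,0
221,male,Health professionals,221,0
231,male,Teaching professionals,231,0
232,male,Research professionals,232,0
24,male,Business and public service professionals,24,0
311,male,Science and engineering technicians,311,0
312,male,Draughts persons and building inspectors,312,0
313,male,Information technology service delivery occupations,313,0
321,male,Health associate professionals,321,0
323,male,Social welfare associate professionals,323,0
331,male,Protective service occupations,331,0
34,male,"Culture, media, and sports occupations",34,0
351,male,Transport associate professionals,351,0
353,male,Business and finance associate professionals,353,0
354,male,Sales and related associate professionals,354,0
356,male,Public service and other associate professionals,356,0
411,male,Administrative occupations: government and related organisations,411,0
412,male,Administrative occupations: finance,412,0
413,male,Administrative occupations: records,413,0
414,male,Administrative occupations: communications,414,0
415,male,Administrative occupations: general,415,0
421,male,Secretarial and related occupations,421,0
511,male,Agricultural trades,511,0
521,male,"Metal forming, welding, and related trades",521,0
522,male,"Metal machining, fitting, and instrument making trades",522,0
523,male,Vehicle trades,523,0
524,male,Electrical trades,524,0
531,male,Construction trades,531,0
532,male,Building trades,532,0
541,male,Textiles and garments trades,541,0
542,male,Printing trades,542,0
543,male,Food preparation trades,543,0
549,male,Skilled trades not elsewhere classified,549,0
611,male,Health care and related personal services,611,0
613,male,Animal care services,613,0
621,male,Leisure and travel service occupations,621,0
622,male,Hairdressers and related occupations,622,0
623,male,Housekeeping occupations,623,0
711,male,Sales assistants and retail cashiers,711,0
712,male,Sales-related occupations,712,0
721,male,Customer service occupations,721,0
811,male,Process operatives,811,0
812,male,Plant and machine operatives,812,0
813,male,Assemblers and routine operatives,813,0
814,male,Construction operatives,814,0
821,male,Transport drivers and operatives,821,0
822,male,Mobile machine drivers and operatives,822,0
911,male,Elementary agricultural occupations,911,0
912,male,Elementary construction occupations,912,0
913,male,Elementary process plant occupations,913,0
914,male,Elementary goods storage occupations,914,0
921,male,Elementary administration occupations,921,0
922,male,Elementary personal services occupations,922,0
923,male,Elementary cleaning occupations,923,0
924,male,Elementary security occupations,924,0
925,male,Elementary sales occupations,925,0
none,male,No occupation reported,,1
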