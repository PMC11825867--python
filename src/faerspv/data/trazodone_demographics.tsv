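# Demographic section counts for trazodone primary-suspect adverse-event
# reports, FAERS 2004Q1-2024Q2 (5199 deduplicated reports, 15161 AE mentions).
# Columns: section <TAB> label <TAB> count <TAB> published_percent
# Sections use their own denominators: report counts for Year/Gender/Age/
# Reporter/Route, entry counts for Outcomes and Indications, reports with a
# known country for the country section, and all reports (including the
# unknown row) for time-to-onset. Rows with an empty percent only complete a
# section's denominator.
Year	2004	138	2.65
Year	2005	115	2.21
Year	2006	122	2.35
Year	2007	87	1.67
Year	2008	105	2.02
Year	2009	188	3.62
Year	2010	132	2.54
Year	2011	193	3.71
Year	2012	95	1.83
Year	2013	114	2.19
Year	2014	203	3.9
Year	2015	376	7.23
Year	2016	300	5.77
Year	2017	309	5.94
Year	2018	460	8.85
Year	2019	357	6.87
Year	2020	489	9.41
Year	2021	434	8.35
Year	2022	328	6.31
Year	2023	391	7.52
Year	2024	263	5.06
Gender	Female	2739	52.68
Gender	Male	2019	38.83
Gender	Unknown	441	8.48
Age	<30	475	9.14
Age	30~40	440	8.46
Age	40~50	672	12.93
Age	50~60	738	14.2
Age	60~70	610	11.73
Age	70~80	373	7.17
Age	>=80	255	4.9
Age	Unknown	1636	31.47
Reporter	Consumer	1923	36.99
Reporter	Physician	1193	22.95
Reporter	Pharmacist	1112	21.39
Reporter	Other health-professional	623	11.98
Reporter	Unknown	335	6.44
Reporter	Lawyer	12	0.23
Reporter	Registered Nurse	1	0.02
Reported countries	United States	3341	82.58
Reported countries	United Kingdom	200	4.94
Reported countries	Canada	183	4.52
Reported countries	Other	78	1.93
Reported countries	Spain	55	1.36
Reported countries	(other known countries)	189	
Route	Other	3005	57.8
Route	Oral	2166	41.66
Route	Transplacental	28	0.54
Outcomes	Other serious	1927	38.94
Outcomes	Hospitalization	1298	26.23
Outcomes	Death	1131	22.85
Outcomes	Life threatening	226	4.57
Outcomes	Disability	195	3.94
Outcomes	Required intervention to Prevent Permanent Impairment/Damage	158	3.19
Outcomes	Congenital anomaly	14	0.28
Time to event onset (days)	<7	534	30.12
Time to event onset (days)	7~30	181	10.21
Time to event onset (days)	30~180	166	9.36
Time to event onset (days)	180~360	52	2.93
Time to event onset (days)	>=360	150	8.46
Time to event onset (days)	Unknown	690	38.92
Indications	Affective disorder	13	0.24
Indications	Agitation	15	0.28
Indications	Antidepressant therapy	36	0.68
Indications	Anxiety	101	1.89
Indications	Anxiety disorder	11	0.21
Indications	Bipolar disorder	22	0.41
Indications	Depression	489	9.17
Indications	Drug abuse	64	1.2
Indications	Insomnia	962	18.04
Indications	Major depression	57	1.07
Indications	Others	293	5.49
Indications	Pain	17	0.32
Indications	Post-traumatic stress disorder	30	0.56
Indications	Product used for unknown indication	1348	25.28
Indications	Schizophrenia	14	0.26
Indications	Sleep disorder	473	8.87
Indications	Sleep disorder therapy	32	0.6
Indications	Somnolence	24	0.45
Indications	Suicide attempt	132	2.48
Indications	Unknown	1200	22.5
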