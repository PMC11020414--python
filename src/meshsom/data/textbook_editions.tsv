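edition_id	year	pages	chapters	new_chapters	removed_chapters	citations_total	citations_indexed	persistence_pct
1st	1967	1629	53	53		2927	585
2nd	1975	2572	52	18	19	9126	2280	44
3rd	1980	3306	57	9	4	17030	4225	56
4th	1985	2055	54	3	6	2091	407	5
5th	1989	2158	50	10	14	3999	780	21
6th	1995	2805	53	8	5	8625	2393	16
7th	2000	3345	55	7	5	10180	4257	23
8th	2005	4064	55	2	2	11795	3780	20
9th	2009	4521	59	4	0	10472	4815	25
10th	2017	4533	62	5	2	9235	4157	26
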