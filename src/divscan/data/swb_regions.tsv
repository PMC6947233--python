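chrom	start_bp	end_bp	length_kb_printed	lowest_adjusted_p	highest_fst	direction	length_consistent
7	89669652	91203503	2918	0.0022	0.16	SJ	0
8	10891925	11400093	508	0.0040	0.13	SJ	1
12	11601991	12104261	502	0.0129	na	SJ	1
12	28794818	29306185	511	0.0009	0.13	SJ	1
13	27280931	27830947	550	0.0031	0.14	SJ	1
19	41459599	41959599	500	0.0247	0.13	SJ	1
22	27935550	31789708	3854	0.0008	0.14	SJ	1
31	13778365	14321247	543	0.00002	na	SJ	1
1	40592555	43510660	2918	0.0230	0.21	NS	1
23	51321303	51844470	523	0.0501	0.15	NS	1
25	5277465	5984107	707	0.0002	0.15	NS	1
25	37351887	37886254	534	0.0071	0.15	NS	1
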