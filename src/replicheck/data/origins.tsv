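chrom	pos	name	trep	fire_sd	rerep_rate
chrI	11200	oriI-01	16.6	5.0	0.02
chrI	33600	oriI-02	41.2	5.0	0.02
chrI	50900	oriI-03	43.4	5.0	0.02
chrI	77100	oriI-04	16.6	5.0	0.02
chrI	96600	oriI-05	17.8	5.0	0.02
chrI	112100	oriI-06	38.4	5.0	0.02
chrI	136100	oriI-07	26.5	5.0	0.02
chrI	150300	oriI-08	35.0	5.0	0.02
chrI	180000	oriI-09	28.0	5.0	0.02
chrI	195800	oriI-10	29.0	5.0	0.02
chrI	215600	oriI-11	36.6	5.0	0.02
chrII	10600	oriII-01	29.2	5.0	0.02
chrII	35300	oriII-02	41.5	5.0	0.02
chrII	54600	oriII-03	40.6	5.0	0.02
chrII	79800	oriII-04	43.6	5.0	0.02
chrII	96200	oriII-05	20.0	5.0	0.02
chrII	118700	oriII-06	29.9	5.0	0.02
chrII	132400	oriII-07	36.3	5.0	0.02
chrII	153100	oriII-08	31.1	5.0	0.02
chrII	173700	oriII-09	35.7	5.0	0.02
chrII	193800	oriII-10	44.1	5.0	0.02
chrII	211400	oriII-11	23.5	5.0	0.02
chrII	236400	oriII-12	44.5	5.0	0.02
chrII	253300	oriII-13	33.4	5.0	0.02
chrII	278300	oriII-14	35.8	5.0	0.02
chrII	297800	oriII-15	35.2	5.0	0.02
chrII	310200	oriII-16	21.4	5.0	0.02
chrII	331800	oriII-17	36.3	5.0	0.02
chrII	357200	oriII-18	35.8	5.0	0.02
chrII	375600	oriII-19	23.8	5.0	0.02
chrII	398900	oriII-20	35.3	5.0	0.02
chrII	410300	oriII-21	25.0	5.0	0.02
chrII	433600	oriII-22	43.7	5.0	0.02
chrII	451900	oriII-23	34.5	5.0	0.02
chrII	477900	oriII-24	27.3	5.0	0.02
chrII	490300	oriII-25	44.3	5.0	0.02
chrII	518000	oriII-26	43.0	5.0	0.02
chrII	530300	oriII-27	29.5	5.0	0.02
chrII	558800	oriII-28	21.3	5.0	0.02
chrII	579200	oriII-29	33.8	5.0	0.02
chrII	595100	oriII-30	33.5	5.0	0.02
chrII	615600	oriII-31	24.0	5.0	0.02
chrII	632400	oriII-32	28.6	5.0	0.02
chrII	654400	oriII-33	26.3	5.0	0.02
chrII	670000	oriII-34	39.8	5.0	0.02
chrII	699600	oriII-35	35.1	5.0	0.02
chrII	714600	oriII-36	28.1	5.0	0.02
chrII	736700	oriII-37	29.7	5.0	0.02
chrII	755400	oriII-38	38.0	5.0	0.02
chrII	774700	oriII-39	38.4	5.0	0.02
chrII	796800	oriII-40	17.6	5.0	0.02
chrIII	16900	oriIII-01	35.6	5.0	0.3
chrIII	36100	oriIII-02	32.1	5.0	0.3
chrIII	59100	oriIII-03	16.1	5.0	0.3
chrIII	73600	oriIII-04	32.1	5.0	0.3
chrIII	96800	oriIII-05	33.4	5.0	0.3
chrIII	113100	oriIII-06	26.5	5.0	0.3
chrIII	139300	oriIII-07	38.7	5.0	0.3
chrIII	152600	oriIII-08	29.8	5.0	0.3
chrIII	178000	oriIII-09	18.0	5.0	0.3
chrIII	203200	oriIII-10	31.3	5.0	0.3
chrIII	223100	oriIII-11	38.4	5.0	0.3
chrIII	236800	oriIII-12	17.4	5.0	0.3
chrIII	260100	oriIII-13	22.2	5.0	0.3
chrIII	276900	oriIII-14	30.9	5.0	0.3
chrIII	292000	ARS317	25.0	5.0	1.0
chrIII	302100	oriIII-15	40.7	5.0	0.3
chrVII	13700	oriVII-01	34.9	5.0	0.02
chrVII	38100	oriVII-02	17.3	5.0	0.02
chrVII	51700	oriVII-03	35.0	5.0	0.02
chrVII	75800	oriVII-04	37.5	5.0	0.02
chrVII	91000	oriVII-05	29.6	5.0	0.02
chrVII	116700	oriVII-06	42.1	5.0	0.02
chrVII	133000	oriVII-07	34.0	5.0	0.02
chrVII	153000	oriVII-08	37.3	5.0	0.02
chrVII	172200	oriVII-09	42.5	5.0	0.02
chrVII	196400	oriVII-10	24.9	5.0	0.02
chrVII	219400	oriVII-11	44.1	5.0	0.02
chrVII	238500	oriVII-12	39.0	5.0	0.02
chrVII	250200	oriVII-13	35.5	5.0	0.02
chrVII	272500	oriVII-14	17.0	5.0	0.02
chrVII	295900	oriVII-15	23.9	5.0	0.02
chrVII	318000	oriVII-16	29.3	5.0	0.02
chrVII	331100	oriVII-17	33.3	5.0	0.02
chrVII	353900	oriVII-18	34.5	5.0	0.02
chrVII	372900	oriVII-19	23.2	5.0	0.02
chrVII	398900	oriVII-20	22.0	5.0	0.02
chrVII	415600	oriVII-21	35.9	5.0	0.02
chrVII	433700	oriVII-22	28.7	5.0	0.02
chrVII	453100	oriVII-23	23.9	5.0	0.02
chrVII	471500	oriVII-24	28.6	5.0	0.02
chrVII	499200	oriVII-25	25.8	5.0	0.02
chrVII	512800	oriVII-26	34.9	5.0	0.02
chrVII	536900	oriVII-27	27.1	5.0	0.02
chrVII	553300	oriVII-28	40.3	5.0	0.02
chrVII	570000	oriVII-29	30.4	5.0	0.02
chrVII	595000	oriVII-30	42.2	5.0	0.02
chrVII	615000	oriVII-31	25.7	5.0	0.02
chrVII	640000	oriVII-32	19.3	5.0	0.02
chrVII	658200	oriVII-33	26.1	5.0	0.02
chrVII	670800	oriVII-34	29.2	5.0	0.02
chrVII	690200	oriVII-35	26.9	5.0	0.02
chrVII	717200	oriVII-36	18.5	5.0	0.02
chrVII	733500	oriVII-37	27.0	5.0	0.02
chrVII	754200	oriVII-38	32.3	5.0	0.02
chrVII	773800	oriVII-39	31.6	5.0	0.02
chrVII	799400	oriVII-40	36.2	5.0	0.02
chrVII	817700	oriVII-41	19.7	5.0	0.02
chrVII	832600	oriVII-42	39.0	5.0	0.02
chrVII	859000	oriVII-43	41.9	5.0	0.02
chrVII	876600	oriVII-44	25.2	5.0	0.02
chrVII	894600	oriVII-45	30.3	5.0	0.02
chrVII	911500	oriVII-46	31.9	5.0	0.02
chrVII	936100	oriVII-47	36.6	5.0	0.02
chrVII	950900	oriVII-48	44.5	5.0	0.02
chrVII	977700	oriVII-49	38.5	5.0	0.02
chrVII	994300	oriVII-50	44.1	5.0	0.02
chrVII	1014800	oriVII-51	15.1	5.0	0.02
chrVII	1031300	oriVII-52	31.7	5.0	0.02
chrVII	1052300	oriVII-53	43.7	5.0	0.02
chrVII	1077400	oriVII-54	41.5	5.0	0.02
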