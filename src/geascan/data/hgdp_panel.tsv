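population	country	n_sampled	virus_diversity
Bantu North East	Kenya	11	49
Bantu South East	South Africa	8	46
Biaka Pygmies	Central African Republic	23	54
Mandenka	Senegal	22	51
Mbuti Pygmies	Democratic Republic of Congo	13	50
San	Namibia	5	42
Yoruba	Nigeria	21	54
Colombians	Colombia	7	49
Karitiana	Brazil	14	55
Maya	Mexico	21	49
Pima	Mexico	14	49
Surui	Brazil	8	55
Balochi	Pakistan	24	45
Brahui	Pakistan	25	45
Burusho	Pakistan	25	45
Hazara	Pakistan	22	45
Kalash	Pakistan	23	45
Makrani	Pakistan	25	45
Pathan	Pakistan	23	45
Sindhi	Pakistan	24	45
Uygur	China	10	47
Cambodians	Cambodia	10	42
Dai	China	10	47
Daur	China	9	47
Han	China	44	47
Hezhen	China	9	47
Japanese	Japan	29	41
Lahu	China	8	47
Miaozu	China	10	47
Mongola	China	10	47
Naxi	China	8	47
Oroqen	China	9	47
She	China	10	47
Tu	China	10	47
Tujia	China	10	47
Xibo	China	9	47
Yakut	Russia	25	48
Yizu	China	10	47
Adygei	Russia	17	48
French	France	28	42
French Basque	France	24	42
North Italian	Italy	13	43
Orcadian	Orkney Islands (Scotland)	15	39
Russian	Russia	25	48
Sardinian	Italy	28	43
Tuscan	Italy	8	43
Bedouin	Israel	46	41
Druze	Israel	42	41
Mozabite	Algeria	29	39
Palestinian	Israel	46	41
NAN Melanesian	Papua New Guinea	11	45
Papuan	Papua New Guinea	17	45
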