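sample_id	rin	a260_230	gnuse_status	gnuse_rank	cv_status	cv_rank	pm_bg_status	pm_bg_rank	array_weight	weight_rank
44N	3	2.41	fail	1	fail	3	fail	1	0.22	1
33T	2.8	2.08	fail	2	fail	5	fail	2	0.28	2
60N	3.2	2.03	fail	3	fail	1	fail	3	0.42	3
63T	3	2.2	fail	4	fail	4	pass		0.59	6
10T	3.2	2.18	fail	5	fail	2	fail	4	0.60	7
56T	3.3	1.87	fail	6	fail	10	fail	5	0.42	4
41T	4.2	2.21	fail	7	fail	9	pass		0.78	8
13N	4.6	2.24	pass		fail	7	pass		0.82	9
15T	4.8	2.15	pass		fail	8	pass		1.07	15
4N	2.6	1.62	pass		pass		pass		0.44	5
18N	7.1	1.66	pass		pass		pass		0.83	10
8T	8.5	2.16	pass		pass		pass		0.85	11
56N	6.5	1.94	pass		pass		pass		0.95	12
20T	7.4	1.6	pass		pass		pass		1.02	13
44T	6.9	1.72	pass		pass		pass		1.03	14
11T	8.6	2.16	pass		pass		pass		1.07	16
60T	6.4	1.64	pass		pass		pass		1.09	17
14T	6.4	1.76	pass		pass		pass		1.09	18
13T	8.3	2	pass		pass		pass		1.11	19
23T	7	2.17	pass		pass		pass		1.18	20
8N	7.1	2.22	pass		pass		pass		1.25	21
18T	7.4	1.85	pass		pass		pass		1.26	22
33N	8.1	1.82	pass		pass		pass		1.45	23
34T	8	2.25	pass		pass		pass		1.49	24
11N	6.8	1.94	pass		pass		pass		1.50	25
20N	7.3	2.11	pass		pass		pass		1.50	26
63N	7.5	2.13	pass		pass		pass		1.61	27
23N	8.4	2.02	pass		pass		pass		1.61	28
34N	8.3	2.21	pass		pass		pass		1.61	29
14N	8.1	2.36	pass		pass		pass		1.74	30
41N	5.4	2.07	pass		pass		pass		1.76	31
10N	7.3	1.78	pass		pass		pass		1.78	32
15N	6.9	2.16	pass		pass		pass		1.90	33
4T	8.4	2.25	pass		pass		pass		2.14	34
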