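label	x	y
E1	0.000000	0.000000
E2	0.000000	0.200000
E3	-0.173205	0.100000
E4	-0.173205	-0.100000
E5	-0.000000	-0.200000
E6	0.173205	-0.100000
E7	0.173205	0.100000
E8	0.000000	0.400000
E9	-0.200000	0.346410
E10	-0.346410	0.200000
E11	-0.400000	0.000000
E12	-0.346410	-0.200000
E13	-0.200000	-0.346410
E14	-0.000000	-0.400000
E15	0.200000	-0.346410
E16	0.346410	-0.200000
E17	0.400000	-0.000000
E18	0.346410	0.200000
E19	0.200000	0.346410
E20	0.000000	0.600000
E21	-0.205212	0.563816
E22	-0.385673	0.459627
E23	-0.519615	0.300000
E24	-0.590885	0.104189
E25	-0.590885	-0.104189
E26	-0.519615	-0.300000
E27	-0.385673	-0.459627
E28	-0.205212	-0.563816
E29	-0.000000	-0.600000
E30	0.205212	-0.563816
E31	0.385673	-0.459627
E32	0.519615	-0.300000
E33	0.590885	-0.104189
E34	0.590885	0.104189
E35	0.519615	0.300000
E36	0.385673	0.459627
E37	0.205212	0.563816
E38	0.000000	0.800000
E39	-0.207055	0.772741
E40	-0.400000	0.692820
E41	-0.565685	0.565685
E42	-0.692820	0.400000
E43	-0.772741	0.207055
E44	-0.800000	0.000000
E45	-0.772741	-0.207055
E46	-0.692820	-0.400000
E47	-0.565685	-0.565685
E48	-0.400000	-0.692820
E49	-0.207055	-0.772741
E50	-0.000000	-0.800000
E51	0.207055	-0.772741
E52	0.400000	-0.692820
E53	0.565685	-0.565685
E54	0.692820	-0.400000
E55	0.772741	-0.207055
E56	0.800000	-0.000000
E57	0.772741	0.207055
E58	0.692820	0.400000
E59	0.565685	0.565685
E60	0.400000	0.692820
E61	0.207055	0.772741
E62	0.000000	1.000000
E63	-0.201299	0.979530
E64	-0.394356	0.918958
E65	-0.571268	0.820763
E66	-0.724793	0.688967
E67	-0.848644	0.528964
E68	-0.937752	0.347305
E69	-0.988468	0.151428
E70	-0.998717	-0.050649
E71	-0.968077	-0.250653
E72	-0.897805	-0.440394
E73	-0.790776	-0.612106
E74	-0.651372	-0.758758
E75	-0.485302	-0.874347
E76	-0.299363	-0.954139
E77	-0.101168	-0.994869
E78	0.101168	-0.994869
E79	0.299363	-0.954139
E80	0.485302	-0.874347
E81	0.651372	-0.758758
E82	0.790776	-0.612106
E83	0.897805	-0.440394
E84	0.968077	-0.250653
E85	0.998717	-0.050649
E86	0.988468	0.151428
E87	0.937752	0.347305
E88	0.848644	0.528964
E89	0.724793	0.688967
E90	0.571268	0.820763
E91	0.394356	0.918958
E92	0.201299	0.979530
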