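lake	transect	size_ha	depth_m	secchi_m	ph	conductivity	hco3	lai	larix_pct	vegetation
09-Tik-05	Tik	0.160	5.0	2.5	7.00	67.0	34.3	1.260	1.75	arctic tundra
09-Tik-08	Tik	0.480	2.9	1.0	6.70	32.0	15.7	0.796	0.54	arctic tundra
09-Tik-09	Tik	0.640	6.3	1.6	6.20	14.0	5.0	1.238	2.88	light northern taiga
09-Tik-13	Tik	0.640	2.5	1.0	7.23	27.0	17.8	1.412	4.47	light northern taiga
09-Tik-14	Tik	0.240	6.3	1.5	6.57	27.0	12.8	1.304	3.53	light northern taiga
07-SA-26	SA	0.160	6.8	4.5	7.32	30.0	16.2	1.118	2.62	arctic tundra
07-SA-31	SA	0.023	6.9	1.8	7.15	20.0	7.0	1.122	4.41	single-tree tundra
07-SA-33	SA	0.240	5.0	1.5	7.20	38.0	19.2	1.182	3.77	light northern taiga
11-CH-02	CH	0.060	3.5	1.7	6.97	51.1	33.3	1.180	2.02	forest tundra
11-CH-06	CH	0.045	4.8	2.5	6.42	35.3	23.0	1.510	1.94	light northern taiga
11-CH-09	CH	0.020	4.8	3.0	5.09	43.2	24.7	1.510	2.97	light northern taiga
11-CH-10	CH	0.105	15.4	4.0	7.09	40.7	23.2	1.512	3.06	light northern taiga
11-CH-11	CH	0.030	19.7	4.7	6.24	47.2	30.1	1.432	1.29	single-tree tundra
11-CH-12	CH	0.030	14.3	5.0	7.50	34.9	31.3	1.060	1.65	single-tree tundra
11-CH-13	CH	0.012	11.1	3.7	6.31	80.1	49.9	1.058	1.65	single-tree tundra
11-CH-14	CH	0.005	6.7	2.5	7.38	39.9	27.5	1.060	1.71	single-tree tundra
11-CH-15	CH	0.045	4.1	2.0	6.90	45.6	23.6	1.060	2.97	single-tree tundra
11-CH-17	CH	0.022	3.4	1.7	7.87	64.2	25.0	1.060	1.74	forest tundra
11-CH-18	CH	0.045	4.8	1.3	8.02	59.0	32.0	1.062	5.42	forest tundra
11-CH-19	CH	0.053	4.4	1.9	7.84	183.2	111.7	1.066	3.87	forest tundra
11-CH-20	CH	0.045	2.7	1.7	7.92	68.3	41.8	1.064	2.58	forest tundra
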