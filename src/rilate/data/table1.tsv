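instrument_id	sample_id	side	critical_extent_um	necrosis_extent_um	frontier_temp_C	rilate_printed
marSeal	1	above	2070	421.9	57.5	20.3
marSeal	2	above	2830	442.6	66.5	15.6
marSeal	3	above	2630	439.7	66.0	16.7
marSeal	4	above	2570	535.3	68.7	20.8
marSeal	5	above	2660	461.5	64.7	17.3
marSeal	6	above	1900	285.7	63.5	15.0
marSeal	7	above	1360	327.8	59.4	24.1
marSeal	8	above	1620	385.1	63.0	23.7
marSeal	9	above	2500	316.2	71.3	12.6
marSeal	10	above	2630	373.5	67.5	14.2
marSeal	11	above	1830	486.8	68.3	26.6
marSeal	12	above	2050	521.7	58.2	25.4
marSeal	13	above	3310	492.8	64.7	15.7
marSeal	14	above	2290	374.6	70.1	16.3
marSeal	15	above	2470	322.8	64.6	13.1
marSeal	1	below	1990	416.2	59.6	20.9
marSeal	2	below	1580	497.6	65.1	31.5
marSeal	3	below	1540	385.9	63.1	25.0
marSeal	4	below	1590	562.2	60.7	35.4
marSeal	5	below	1220	606.8	57.9	49.7
marSeal	6	below	1590	384.4	61.3	24.1
marSeal	7	below	2030	522.7	66.8	25.7
marSeal	8	below	1430	494.5	62.1	34.5
marSeal	9	below	1980	332.6	67.5	16.8
marSeal	10	below	1660	331.7	62.6	19.9
marSeal	11	below	2480	407.1	70.5	16.4
marSeal	12	below	1330	514.4	59.9	38.6
marSeal	13	below	1520	373.2	64.6	24.5
marSeal	14	below	2010	295.7	65.8	14.7
marSeal	15	below	1550	275.6	63.8	17.8
BiCision	1	above	1600	886.6	56.5	55.4
BiCision	2	above	1480	733.8	56.0	49.6
BiCision	3	above	2750	956.8	65.2	34.8
BiCision	4	above	1950	654.8	58.7	33.6
BiCision	5	above	1760	479.1	57.9	27.2
BiCision	6	above	1650	518.4	57.3	31.4
BiCision	7	above	2600	497.9	64.0	19.2
BiCision	8	above	1560	654.8	60.6	42.0
BiCision	9	above	2270	768.1	60.9	33.8
BiCision	10	above	2340	597.0	61.7	25.5
BiCision	11	above	1730	499.5	59.3	28.9
BiCision	12	above	2970	567.0	64.6	19.0
BiCision	13	above	1400	582.9	55.4	41.6
BiCision	14	above	3090	811.1	70.6	26.2
BiCision	15	above	1330	431.5	57.6	33.4
BiCision	1	below	1270	694.7	52	54.7
BiCision	2	below	1440	688.3	56.6	47.8
BiCision	3	below	2010	973.6	51.2	48.4
BiCision	4	below	730	618.2	52.1	84.7
BiCision	5	below	720	535.4	52	74.4
BiCision	6	below	1530	542.8	59.8	34.5
BiCision	7	below	1490	596.4	64.7	40.0
BiCision	8	below	820	603.1	54.2	73.5
BiCision	9	below	1280	696.9	54.7	54.4
BiCision	10	below	920	556.8	53.8	60.5
BiCision	11	below	820	592.8	53.3	72.3
BiCision	12	below	890	588.5	53	66.1
BiCision	13	below	870	748.8	51.3	86.1
BiCision	14	below	1550	682.3	62.4	44.0
BiCision	15	below	1390	561.3	58.1	40.4
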