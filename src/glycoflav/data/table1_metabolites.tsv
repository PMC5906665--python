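name	rt_min	mz	fragments
Alanine	1.57	90.9750	44.0
Arginine	1.41	175.1991	116.1,157.2,130.0,65.4
Asparagine	1.72	133.0450	74.0,123.1,112.1,83.1
Aspartic acid	1.57	134.0986	88.1,116.1,74.1,70.0,68.0
Glutamic acid	1.57	148.0533	84.1,130.1,102.1,79.7
Histidine	1.42	156.0859	110.1,93.1,83.1,67.4
Isoleucine	1.72	132.1990	86.2,69.1,67.1,56.1
Leucine	2.44	132.0986	86.1,69.1,67.1,56.1
Lysine	1.57	147.1878	84.2,130.1
Methionine	1.64	150.2420	61.2,104.3,75.0,81.0,53.9
Phenylalanine	3.67	166.1763	120.1,103.7,93.4,72.2
Proline	1.57	116.0633	70.0,66.6,63.9
Serine	1.78	106.0925	60.0
Threonine	1.57	120.0637	74.0,55.8
Tryptophan	4.95	205.1994	146.2,118.1,170.3,188.2,91.0
Tyrosine	2.41	182.2013	91.2,136.2,119.3,76.9,136.2
Valine	1.64	118.0789	72.2,69.9,52.4
Glutathione (oxidized)	2.40	612.1558	355.7,484.3,248.5,305.2,538.5,191.0
Apigenin	11.67	271.0601	153.1,243.2,229.1,197.2,145.2
C-hexosyl-apigenin O-feruloylhexoside	8.24	771.2132	177.1,433.1,337.0,591.1,145.1
C-hexosyl-apigenin O-p-coumaroylhexoside	8.60	741.2027	147.2,579.3,367.1,337.0,207.2
C-hexosyl-chrysoeriol O-feruloylhexoside	8.19	801.2243	463.1,397.1,367.1,177.1,343.1,313.1
C-hexosyl-luteolin O-feruloylhexoside	7.58	787.2082	449.1,383.1,329.1,177.1
Chrysoeriol	11.93	301.0707	286.0,258.1
Chrysoeriol 5-O-hexoside	8.39	463.1233	301.1,286.3,258.4
Chrysoeriol 7-O-hexoside	8.99	463.1234	301.1,286.3,258.4
Chrysoeriol C-hexoside	8.09	463.1239	313.1,367.0,343.0,298.0
C-pentosyl-apeignin O-feruloylhexoside	9.23	741.2027	177.1,145.1,283.3,367.2
C-pentosyl-apigenin O-hexoside	8.32	565.1554	367.1,403.0,337.1,313.1,283.0
C-pentosyl-apigenin O-p-coumaroylhexoside	9.20	711.1919	367.1,549.4,349.1,337.1,283.2
C-pentosyl-C-hexosyl-apigenin	7.02	565.1553	505.2,547.3,475.2,445.2,511.3,415.2
C-pentosyl-chrysoeriol O-feruloylhexoside	9.18	771.2120	177.0,433.1,337.0,591.1,145.1
C-pentosyl-chrysoeriol O-hexoside	8.50	595.1663	397.1,433.1,379.2,367.2,343.2
C-pentosyl-luteolin O-hexoside	7.70	581.1505	383.2,419.1,365.2,353.2,329.2
di-C,C-hexosyl-methylluteolin	5.99	625.1766	607.2,463.2,391.1,367.1,343.1
di-C,C-pentosyl-apigenin	7.62	535.1438	499.3,481.3,433.4,381.5,349.7
di-C,C-pentosyl-luteolin	7.21	551.1398	497.1,515.2,407.1,395.1,365.1
Eriodictyol C-hexoside	7.29	450.9858	331.1,433.1,385.1,355.1,301.2
Eriodictyol O-malonylhexoside	9.90	536.9119	289.0
Luteolin	10.6	287.0544	153.0,135.0
Luteolin 6-C-glucoside	7.16	449.1078	299.2,359.1,329.1,283.2
Luteolin C-hexoside isomer	7.50	449.1087	299.2,413.1,353.1,329.2
Luteolin O-malonylhexoside	10.2	534.9318	287.0
Naringenin	11.7	273.0757	153.0,147.0,119.0
Naringenin O-malonylhexoside	10.7	520.9838	273.0
Quercetin O-malonylhexoside	9.90	551.0106	303.0
Resokaempferol 7-O-hexoside	9.20	433.1137	271.1,379.2,313.1,153.2
Sakuranetin	14.44	286.9843	167.1,153.2
Tricetin O-malonylhexoside	10.80	550.9927	303.0
Tricin	11.85	331.0811	315.0,285.0,258.0,243.0,153.0
Tricin 5-O-hexoside derivative	9.42	535.1091	331.1,315.0,287.1,270.1,233.2
Tricin derivative	9.52	647.2059	331.0,315.0,270.1,157.2
Tricin O-hexoside derivative	13.26	671.1965	509.1,631.4,491.1,331.1
Tricin O-malonylhexoside	10.52	579.1344	331.1,535.1,493.1,315.2,270.2
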