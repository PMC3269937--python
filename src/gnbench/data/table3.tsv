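run	tap5	tap10	tap20
T63_R1	0.0340	0.0488	0.0725
T63_R2	0.0296	0.0458	0.0643
T65_R1	0.0714	0.0986	0.1048
T65_R2	0.0915	0.1097	0.1183
T68_R1	0.1621	0.1876	0.2049
T68_R2	0.1285	0.1460	0.1782
T70_R1	0.0566	0.0566	0.0566
T70_R2	0.0622	0.0622	0.0622
T70_R3	0.0718	0.0718	0.0718
T74_R1	0.2137	0.2509	0.2509
T74_R2	0.2083	0.2480	0.2480
T74_R3	0.2099	0.2495	0.2495
T78_R1	0.0584	0.0741	0.1129
T78_R2	0.0847	0.1202	0.1706
T78_R3	0.0847	0.1128	0.1426
T80_R1	0.1084	0.1581	0.1646
T80_R2	0.0382	0.0516	0.0588
T80_R3	0.0329	0.0437	0.0521
T83_R1	0.3254	0.3538	0.3535
T83_R2	0.3216	0.3435	0.3435
T83_R3	0.3297	0.3514	0.3514
T89_R1	0.1205	0.1205	0.1363
T89_R2	0.1553	0.1553	0.1652
T89_R3	0.1295	0.1548	0.1548
T93_R1	0.1651	0.1902	0.2075
T93_R2	0.1560	0.1858	0.2062
T93_R3	0.1662	0.1916	0.2096
T97_R1	0.0727	0.0939	0.1026
T97_R2	0.0649	0.0872	0.0974
T97_R3	0.0727	0.0939	0.1026
T98_R1	0.2835	0.3012	0.3103
T98_R2	0.2909	0.3079	0.3087
T98_R3	0.3013	0.3183	0.3303
T101_R1	0.1896	0.2288	0.2385
T101_R2	0.1672	0.2150	0.2418
T101_R3	0.1812	0.2141	0.2425
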