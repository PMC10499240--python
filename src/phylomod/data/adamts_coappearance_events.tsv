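node	paralog_ancestor	descendants	ppis	modules
G4	0	ADAMTS-1	HPX DKK3	B561 B1646 B1661 B1657 B1659 B608 B1658 B605 B1668 B1647 B1645
G8	0	ADAMTS-1	A2M	B1673
G10	0	ADAMTS-1	FURIN	B687 B882 B1283 B1665 B1672 B686
G13	0	ADAMTS-4	RELN	B1950
G15	0	ADAMTS-4	A2M FN1 BGN COMP LRP1	B1693 B1675 B1678 B1497 B1674 B1496 B1692 B1676
G19	0	ADAMTS-4	FURIN	B1691 B1689 B1677 B1687 B1842 B1683
G23	0	ADAMTS-8	SPP1	B1545 B1552
G59	0	ADAMTS-5	NCAN CILP MATN4 FMOD SDC1 ITIH2 TNC TIMP3 MMP13 FBLN2 CILP2 ADAMTS5	B1583 B1595 B1610 B1945 B1575 B1577 B1598 B1944 B1591 B1592
G61	0	ADAMTS-5	DCN PRELP	B491
G63	0	ADAMTS-5	COL2A1 COL3A1 FN1 BGN RELN	B657 B1578 B658 B1608
G65	0	ADAMTS-5	A2M LRP1	B1602 B1605 B1593 B1594 B2029 B1588 B1601 B1607 B1617 B1603 B1580 B686
G71	0	ADAMTS-9	RNF123	B522
G75	0	ADAMTS-9	FN1	B974 B1734 B1714 B976 B973 B963 B983 B917 B993 B978 B1702 B873 B1708
G91	1	ADAMTS-9, -20	LRP1	B1715 B858 B949 B1958 B888 B946 B1707 B1283 B854 B836 B987 B835 B911 B860 B856 B889 B1704 B398 B913 B820 B1705 B1728 B939 B865 B910 B400
G96	1	ADAMTS-1, -4, -5, -8, -9, -15, -20	VCAN ACAN	B773 B781
G103	0	ADAMTS-6	ERP29 SDC4 NEK4 SNTA1 LTBP1 RNF2	B1864 B919
G114	0	ADAMTS-10	FBN1	B671 B676 B683 B606 B673 B702 B674
G128	0	Papilin	PKM THOP1 DPY19L3 KLHL36 ZNF507 TFAP2C KIF2C NIF3L1	B2223 B2233 B2265 B2253 B2222 B2214 B2268 B2257 B2241 B2240 B2255 B2251 B2228 B2254 B2232 B2252
G141	0	ADAMTS-12	HELS72 FKBP9 CALM2 USF1 PPM1A MEOX2 MYL6 SP3 USF2 RUFY3 UBR1 SNRK	B1318
G143	0	ADAMTS-12	NCAN	B1298 B1262 B687 B1249 B1320 B1296 B1287 B1290 B1286 B1299 B1253 B1300 B1260 B1291 B1325 B1336 B1245 B1297
G152	0	ADAMTS-7	CTSB	B560 B1919 B1918 B1917
G154	0	ADAMTS-7	COL5A1 COL1A2 CST3 COL1A1 COL3A1 FN1 COL5A2 COL6A3 HLAA	B1450 B1454 B1444 B1436 B1287 B1426 B1470 B1290 B1286 B1453 B1455 B1443 B1433 B1451 B1435 B1430
G160	0	ADAMTS-7	A2M	B1923 B1431 B1921 B1924 B1432
G161	1	ADAMTS-7, -12	GRN CCN2 COMP	B1289 B1456 B1331 B1272 B1460 B1993 B594 B592 B1305 B1429 B1283 B1332 B911 B1269 B1317 B1306 B1811 B1315 B1307 B1995 B1288 B1328 B1316 B1247 B910
G169	0	ADAMTS-18	B3GLCT	B1096
G171	0	ADAMTS-18	ALB	B477 B1073 B1095
G182	0	ADAMTS-16	FN1	B1025 B1012 B1057 B1893 B1004 B1003 B1894
G221	0	ADAMTSL-6	FBN1	B2130 B2163 B2155 B2145 B519 B2353 B2160 B2156 B2180 B2132 B2140 B509 B2124
G228	0	ADAMTSL-4	GLRX3 KRTAP108 KRTAP11	B2419 B2422 B2417 B2418 B2421 B2420
G230	0	ADAMTSL-4	EFEMP2 COL5A1 ITGB4 EGFL9 COL1A2 CLEC18A CYSRT1 US26 LCE2B PLSCR1 ADAM12 FRS3 SPRY2 PRKAB2 TLL1 MAPKBP1 SORBS3 EIF4E2 STK16 FARS2 BAG4 TOP3B COL1A1 COL2A1 COL3A1 ITGB2 COL5A2 CTSB CST2 GIP COL11A1 BMP1 COL11A2 HGF FAH VCAM1 SPINK2 FLNA GATA2 LMO2 LMO1 COL5A3 KRTAP59 COL8A1 CFP AQP1 HOXC8 OTX1 NTF4 PTGER3 HOXA1 FXR1 KRTAP101 KRTAP103 KRTAP105 KRTAP109 KRTAP1011 FKBP1B CREB5 TNK2 KIF1A PIN1 FHL3 DGCR6 DIP2A GNMT MVP TCEA2 TRIP6 LONRF1 COL24A1 KRTAP212 MGAT5B MIIP LCE3C LCE3E LCE1C LCE1B LCE4A LCE2D VASN KRTAP56 MORN3 LRFN4 SPATA8 DLK2 ADAMTSL4 ADAMTSL5 KRTAP52 KCTD9 PID1 ATG9A NEK8 TMEM150A TRIM42 CFAP206 COL27A1 NATD1 CATSPER1 DBF4B ZNF417 LGALS14 RAB2B LRRC29 MYLIP SUSD6 SMARCC1 FBXW5 DISP1 NTAQ1 OLFM3 RCHY1 TSSK3 ZNF587 CYP2S1 KRTAP412 APOL6 TAPBPL DGCR6L KRTAP94 KRTAP92 KRTAP411 KRTAP42 ASPSCR1 NMUR2 CXCL16 RHOJ BANF2 FAM124B ARNT2 SLC6A20 FBXO6 SHFL CPNE7 TUBGCP4 SLC23A1 MID2 DNPEP GNE EXOSC1 SALL2 AMMECR1 CHCHD2	B2182 B2181 B2183 B2195 B2188 B2194 B2189 B2196 B2208
G235	1	ADAMTSL-4, -6	NUFIP2	B2173 B1188 B2168 B2153 B592 B2174 B2203 B2139 B2210 B2147 B2199 B2200 B2201 B2172
G248	0	ADAMTSL-2	FBN1 HOXA1 LOXL3 NECAB2	B2310 B2378 B2377 B2299 B2385 B2301 B2379 B2380 B1820 B2381
G258	0	ADAMTSL-3	CYSRT1 GLRX3 KRTAP23 NOTCH2NLC KRTAP123 KRTAP103 KRTAP106 KRTAP108 KRTAP11 KRT40 KRTAP57 NOTCH2NLA MDFI KRTAP32 KRTAP24	B2084 B2071 B657 B2091 B2076 B2082 B2074 B519 B2102 B1287 B2079 B2042 B2391 B2072 B2395 B2394 B2078 B2087 B2393
G269	0	ADAMTSL-1	MMP10 FHL2 ACOX1 B3GLCT RSPRY1 WDCP	B2401 B2407 B2403 B2405 B2102 B2411 B2096 B2409
G271	0	ADAMTSL-1	GRN	B2105 B2114 B2098 B2107 B2113 B2110 B2106 B2109 B2112 B2104 B2108 B2344
G281	0	ADAMTSL-5	CYSRT1 KRAS NOTCH2NLC KRTAP59 FBN1 KRTAP103 FHL5 ADAMTSL4 NOTCH2NLA	B2283 B2285 B2280 B2275 B2290 B2288 B2434
G299	0	ADAMTS-13	F8 VWF	B1191 B1180 B1206 B1159 B1190 B1204 B1181 B1197 B1199 B1900 B1897
G315	0	ADAMTS-3	CCN2	B1424
G324	0	ADAMTS-2	ALB HPX DCN CTSB DKK3	B1621 B1640 B1623 B1618 B1627 B1620 B1629
G326	0	ADAMTS-2	A2M	B1641 B1638 B510 B1626 B1643
G328	0	ADAMTS-2	CST3 COL6A3 PRELP	B1644 B563 B1636 B1631 B1632 B1835
G334	0	ADAMTS-14	A2M ALB HPX DCN CTSB VCAN DKK3	B1485 B1499 B1486 B1497 B1493 B1410 B1496 B1481 B1498 B1472
G336	0	ADAMTS-14	CST3 COL6A3	B1480
G340	0	ADAMTS-14	PRELP	B1474
G341	1	ADAMTS-2, -3, -14	COL5A1 COL1A2 TLL1 F13A1 CFB C3 KNG1 IGHG3 COL1A1 COL2A1 COL3A1 COL4A1 APOA1 APOA2 APOH FN1 AHSG GC ANXA1 COL5A2 KLK1 ANXA2 MMP3 CFH VIM LGALS1 CTSH C4B COL11A1 COL6A1 COL6A2 BMP1 ANXA8 COL11A2 MIF TCN2 OGN BGN MPZ CTSS COL5A3 GRN HLAA SERPINB6 LGALS7 LUM ACTA2 HBB CAV1 TGFBR3 COL14A1 DPT TMED1 ITIH4 POSTN PDIA6 PCOLCE CDSN COL24A1 SUSD4 DMKN CAVIN1 AEBP2 COL27A1 UNC80 CPA4	B1404 B1340 B1378 B1350 B1391 B1360 B1380 B1492 B1407 B1415 B1399 B1341 B1394 B1362 B1349 B1393 B1403 B1374 B1483 B1390 B1637 B1409
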