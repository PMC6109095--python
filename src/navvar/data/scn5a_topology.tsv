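# Membrane topology of human Nav1.5 (SCN5A isoform 1, 2016 residues).
# Boundaries follow NCBI/UniProt-style annotation of the four homologous
# domains (six transmembrane segments each), the intra-domain loops, the
# three cytoplasmic inter-domain linkers and both termini. Coordinates are
# 1-based inclusive and must tile 1..2016; edit and re-validate to swap in
# an alternative annotation.
# length=2016
name	kind	domain	segment	start	end	side
N	terminus	0	0	1	126	cytoplasmic
D1S1	segment	1	1	127	145	transmembrane
D1L12	segment-linker	1	0	146	153	extracellular
D1S2	segment	1	2	154	172	transmembrane
D1L23	segment-linker	1	0	173	186	cytoplasmic
D1S3	segment	1	3	187	205	transmembrane
D1L34	segment-linker	1	0	206	209	extracellular
D1S4	segment	1	4	210	228	transmembrane
D1L45	segment-linker	1	0	229	244	cytoplasmic
D1S5	segment	1	5	245	263	transmembrane
D1L56	segment-linker	1	0	264	393	extracellular
D1S6	segment	1	6	394	419	transmembrane
L12	domain-linker	0	0	420	711	cytoplasmic
D2S1	segment	2	1	712	730	transmembrane
D2L12	segment-linker	2	0	731	738	extracellular
D2S2	segment	2	2	739	757	transmembrane
D2L23	segment-linker	2	0	758	771	cytoplasmic
D2S3	segment	2	3	772	790	transmembrane
D2L34	segment-linker	2	0	791	804	extracellular
D2S4	segment	2	4	805	823	transmembrane
D2L45	segment-linker	2	0	824	838	cytoplasmic
D2S5	segment	2	5	839	857	transmembrane
D2L56	segment-linker	2	0	858	931	extracellular
D2S6	segment	2	6	932	956	transmembrane
L23	domain-linker	0	0	957	1200	cytoplasmic
D3S1	segment	3	1	1201	1219	transmembrane
D3L12	segment-linker	3	0	1220	1230	extracellular
D3S2	segment	3	2	1231	1249	transmembrane
D3L23	segment-linker	3	0	1250	1262	cytoplasmic
D3S3	segment	3	3	1263	1281	transmembrane
D3L34	segment-linker	3	0	1282	1293	extracellular
D3S4	segment	3	4	1294	1312	transmembrane
D3L45	segment-linker	3	0	1313	1335	cytoplasmic
D3S5	segment	3	5	1336	1354	transmembrane
D3L56	segment-linker	3	0	1355	1445	extracellular
D3S6	segment	3	6	1446	1470	transmembrane
L34	domain-linker	0	0	1471	1523	cytoplasmic
D4S1	segment	4	1	1524	1542	transmembrane
D4L12	segment-linker	4	0	1543	1553	extracellular
D4S2	segment	4	2	1554	1572	transmembrane
D4L23	segment-linker	4	0	1573	1584	cytoplasmic
D4S3	segment	4	3	1585	1603	transmembrane
D4L34	segment-linker	4	0	1604	1622	extracellular
D4S4	segment	4	4	1623	1641	transmembrane
D4L45	segment-linker	4	0	1642	1658	cytoplasmic
D4S5	segment	4	5	1659	1677	transmembrane
D4L56	segment-linker	4	0	1678	1760	extracellular
D4S6	segment	4	6	1761	1785	transmembrane
C	terminus	0	0	1786	2016	cytoplasmic
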