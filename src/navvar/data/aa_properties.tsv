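# Per-residue physico-chemical property tables (one column per property).
# mass: average residue mass in Da (monomer minus water).
# buried_pct: percentage of occurrences buried in folded proteins.
# vdw_volume: van der Waals side-chain volume, cubic Angstrom.
# polarity: polarity ranking (Grantham scale).
# charge: net charge at physiological pH in elementary units (D,E=-1; K,R=+1; H=0).
# hydrophobicity: hydropathy ranking (Kyte-Doolittle).
# helix_propensity: alpha-helix propensity (Chou-Fasman P-alpha).
aa	mass	buried_pct	vdw_volume	polarity	charge	hydrophobicity	helix_propensity
A	71.0788	38.0	67	8.1	0	1.8	1.42
C	103.1388	47.0	86	5.5	0	2.5	0.70
D	115.0886	14.5	91	13.0	-1	-3.5	1.01
E	129.1155	20.0	109	12.3	-1	-3.5	1.51
F	147.1766	48.0	135	5.2	0	2.8	1.13
G	57.0519	37.0	48	9.0	0	-0.4	0.57
H	137.1411	19.0	118	10.4	0	-3.2	1.00
I	113.1594	65.0	124	5.2	0	4.5	1.08
K	128.1741	4.2	135	11.3	1	-3.9	1.16
L	113.1594	41.0	124	4.9	0	3.8	1.21
M	131.1926	50.0	124	5.7	0	1.9	1.45
N	114.1038	10.0	96	11.6	0	-3.5	0.67
P	97.1167	24.0	90	8.0	0	-1.6	0.57
Q	128.1307	6.3	114	10.5	0	-3.5	1.11
R	156.1875	0.0	148	10.5	1	-4.5	0.98
S	87.0782	24.0	73	9.2	0	-0.8	0.77
T	101.1051	25.0	93	8.6	0	-0.7	0.83
V	99.1326	56.0	105	5.9	0	4.2	1.06
W	186.2132	23.0	163	5.4	0	-0.9	1.08
Y	163.1760	13.0	141	6.2	0	-1.3	0.69
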