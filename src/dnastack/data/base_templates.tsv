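# Idealized planar nucleobase geometries (synthetic, MMFF-relaxed free
# bases flattened onto their least-squares plane). Standard frame:
# base plane = xy, glycosidic anchor (N9 purine / N1 pyrimidine) at the
# origin, glycosidic substituent H along -y. Columns: base, atom, element,
# x, y, z (Angstrom). 'C+' is N3-protonated cytosine.
base	atom	element	x	y	z
A	C2	C	-3.222582	1.445866	0.000000
A	C4	C	-1.113232	0.788126	0.000000
A	C5	C	-0.635525	2.085323	0.000000
A	C6	C	-1.599846	3.105982	0.000000
A	C8	C	1.091210	0.825817	0.000000
A	N1	N	-2.907600	2.759802	0.000000
A	N3	N	-2.390688	0.383706	0.000000
A	N6	N	-1.278709	4.455959	0.000000
A	N7	N	0.746258	2.095733	0.000000
A	N9	N	0.000000	0.000000	0.000000
A	H2	H	-4.284578	1.217557	0.000000
A	H61	H	-0.335476	4.660207	0.000000
A	H62	H	-2.027177	5.042088	0.000000
A	H8	H	2.104356	0.445249	0.000000
A	H9	H	0.000000	-1.007763	0.000000
G	C2	C	-3.244199	1.361898	0.000000
G	C4	C	-1.102792	0.798799	0.000000
G	C5	C	-0.617789	2.084589	0.000000
G	C6	C	-1.580375	3.163952	0.000000
G	C8	C	1.093904	0.825603	0.000000
G	N1	N	-2.888306	2.696063	0.000000
G	N2	N	-4.574644	1.099289	0.000000
G	N3	N	-2.385593	0.377134	0.000000
G	N7	N	0.753608	2.099133	0.000000
G	N9	N	-0.000000	0.000000	0.000000
G	O6	O	-1.319878	4.362925	0.000000
G	H1	H	-3.594177	3.409293	0.000000
G	H21	H	-5.174102	1.712021	0.000000
G	H22	H	-4.770795	0.117890	0.000000
G	H8	H	2.105011	0.441155	0.000000
G	H9	H	-0.000000	-1.008784	0.000000
C	C2	C	-1.248312	0.575222	0.000000
C	C4	C	-0.232969	2.640385	0.000000
C	C5	C	1.122059	2.040676	0.000000
C	C6	C	1.160612	0.711009	0.000000
C	N1	N	-0.000000	0.000000	0.000000
C	N3	N	-1.327731	1.943220	0.000000
C	N4	N	-0.367373	4.000237	0.000000
C	O2	O	-2.237622	-0.151354	0.000000
C	H1	H	-0.000000	-1.010230	0.000000
C	H41	H	-1.321216	4.290668	0.000000
C	H42	H	0.320594	4.549967	0.000000
C	H5	H	1.999693	2.668042	0.000000
C	H6	H	2.087136	0.148686	0.000000
C+	C2	C	-1.237624	0.572989	0.000000
C+	C4	C	-0.167355	2.737765	0.000000
C+	C5	C	1.195841	2.008035	0.000000
C+	C6	C	1.190856	0.672938	0.000000
C+	N1	N	-0.000000	0.000000	0.000000
C+	N3	N	-1.241125	1.987794	0.000000
C+	N4	N	-0.169382	4.050419	0.000000
C+	O2	O	-2.310426	0.005154	0.000000
C+	H1	H	-0.000000	-1.016793	0.000000
C+	H3	H	-2.155923	2.410619	0.000000
C+	H41	H	-1.027625	4.586979	0.000000
C+	H42	H	0.700375	4.572087	0.000000
C+	H5	H	2.121637	2.570962	0.000000
C+	H6	H	2.099313	0.075584	0.000000
T	C2	C	-1.232977	0.591856	0.000000
T	C4	C	-0.114493	2.746708	0.000000
T	C5	C	1.192529	2.035408	0.000000
T	C6	C	1.175394	0.696638	0.000000
T	C7	C	2.431903	2.866969	0.000000
T	N1	N	0.000000	0.000000	0.000000
T	N3	N	-1.230405	1.956621	0.000000
T	O2	O	-2.268412	-0.064902	0.000000
T	O4	O	-0.183685	3.971205	0.000000
T	H1	H	0.000000	-1.013839	0.000000
T	H3	H	-2.125489	2.418703	0.000000
T	H6	H	2.083989	0.102268	0.000000
T	H71	H	2.466374	3.505150	0.000000
T	H72	H	2.466372	3.505147	0.000000
T	H73	H	3.335223	2.247750	0.000000
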