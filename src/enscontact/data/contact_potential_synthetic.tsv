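# Synthetic pairwise contact potential (kcal/mol-like units).
# Hydrophobic-attraction surrogate derived from Kyte-Doolittle scores:
# e(a,b) = -0.35*((h_a+4.5)+(h_b+4.5)); swap via config for a published table.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-4.410	-4.655	-2.555	-2.555	-4.760	-3.640	-2.660	-5.355	-2.415	-5.110	-4.445	-2.555	-3.220	-2.555	-2.205	-3.500	-3.535	-5.250	-3.465	-3.325
C	-4.655	-4.900	-2.800	-2.800	-5.005	-3.885	-2.905	-5.600	-2.660	-5.355	-4.690	-2.800	-3.465	-2.800	-2.450	-3.745	-3.780	-5.495	-3.710	-3.570
D	-2.555	-2.800	-0.700	-0.700	-2.905	-1.785	-0.805	-3.500	-0.560	-3.255	-2.590	-0.700	-1.365	-0.700	-0.350	-1.645	-1.680	-3.395	-1.610	-1.470
E	-2.555	-2.800	-0.700	-0.700	-2.905	-1.785	-0.805	-3.500	-0.560	-3.255	-2.590	-0.700	-1.365	-0.700	-0.350	-1.645	-1.680	-3.395	-1.610	-1.470
F	-4.760	-5.005	-2.905	-2.905	-5.110	-3.990	-3.010	-5.705	-2.765	-5.460	-4.795	-2.905	-3.570	-2.905	-2.555	-3.850	-3.885	-5.600	-3.815	-3.675
G	-3.640	-3.885	-1.785	-1.785	-3.990	-2.870	-1.890	-4.585	-1.645	-4.340	-3.675	-1.785	-2.450	-1.785	-1.435	-2.730	-2.765	-4.480	-2.695	-2.555
H	-2.660	-2.905	-0.805	-0.805	-3.010	-1.890	-0.910	-3.605	-0.665	-3.360	-2.695	-0.805	-1.470	-0.805	-0.455	-1.750	-1.785	-3.500	-1.715	-1.575
I	-5.355	-5.600	-3.500	-3.500	-5.705	-4.585	-3.605	-6.300	-3.360	-6.055	-5.390	-3.500	-4.165	-3.500	-3.150	-4.445	-4.480	-6.195	-4.410	-4.270
K	-2.415	-2.660	-0.560	-0.560	-2.765	-1.645	-0.665	-3.360	-0.420	-3.115	-2.450	-0.560	-1.225	-0.560	-0.210	-1.505	-1.540	-3.255	-1.470	-1.330
L	-5.110	-5.355	-3.255	-3.255	-5.460	-4.340	-3.360	-6.055	-3.115	-5.810	-5.145	-3.255	-3.920	-3.255	-2.905	-4.200	-4.235	-5.950	-4.165	-4.025
M	-4.445	-4.690	-2.590	-2.590	-4.795	-3.675	-2.695	-5.390	-2.450	-5.145	-4.480	-2.590	-3.255	-2.590	-2.240	-3.535	-3.570	-5.285	-3.500	-3.360
N	-2.555	-2.800	-0.700	-0.700	-2.905	-1.785	-0.805	-3.500	-0.560	-3.255	-2.590	-0.700	-1.365	-0.700	-0.350	-1.645	-1.680	-3.395	-1.610	-1.470
P	-3.220	-3.465	-1.365	-1.365	-3.570	-2.450	-1.470	-4.165	-1.225	-3.920	-3.255	-1.365	-2.030	-1.365	-1.015	-2.310	-2.345	-4.060	-2.275	-2.135
Q	-2.555	-2.800	-0.700	-0.700	-2.905	-1.785	-0.805	-3.500	-0.560	-3.255	-2.590	-0.700	-1.365	-0.700	-0.350	-1.645	-1.680	-3.395	-1.610	-1.470
R	-2.205	-2.450	-0.350	-0.350	-2.555	-1.435	-0.455	-3.150	-0.210	-2.905	-2.240	-0.350	-1.015	-0.350	-0.000	-1.295	-1.330	-3.045	-1.260	-1.120
S	-3.500	-3.745	-1.645	-1.645	-3.850	-2.730	-1.750	-4.445	-1.505	-4.200	-3.535	-1.645	-2.310	-1.645	-1.295	-2.590	-2.625	-4.340	-2.555	-2.415
T	-3.535	-3.780	-1.680	-1.680	-3.885	-2.765	-1.785	-4.480	-1.540	-4.235	-3.570	-1.680	-2.345	-1.680	-1.330	-2.625	-2.660	-4.375	-2.590	-2.450
V	-5.250	-5.495	-3.395	-3.395	-5.600	-4.480	-3.500	-6.195	-3.255	-5.950	-5.285	-3.395	-4.060	-3.395	-3.045	-4.340	-4.375	-6.090	-4.305	-4.165
W	-3.465	-3.710	-1.610	-1.610	-3.815	-2.695	-1.715	-4.410	-1.470	-4.165	-3.500	-1.610	-2.275	-1.610	-1.260	-2.555	-2.590	-4.305	-2.520	-2.380
Y	-3.325	-3.570	-1.470	-1.470	-3.675	-2.555	-1.575	-4.270	-1.330	-4.025	-3.360	-1.470	-2.135	-1.470	-1.120	-2.415	-2.450	-4.165	-2.380	-2.240
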