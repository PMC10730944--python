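# Electron scattering factors, five-Gaussian parameterisation
# fe(q) = sum_i a_i * exp(-b_i * (q/2)^2), q in cycles/Angstrom (s = q/2 = sin(theta)/lambda)
# Source: International Tables for Crystallography Vol. C, Table 4.3.2.2 (Peng et al. 1996),
# as distributed with gemmi 0.7.4.  Version 1.
element	a1	a2	a3	a4	a5	b1	b2	b3	b4	b5
H	0.0349	0.1201	0.197	0.0573	0.1195	0.5347	3.5867	12.3471	18.9525	38.6269
C	0.0893	0.2563	0.757	1.0487	0.3575	0.2465	1.71	6.4094	18.6113	50.2523
N	0.1022	0.3219	0.7982	0.8197	0.1715	0.2451	1.7481	6.1925	17.3894	48.1431
O	0.0974	0.2921	0.691	0.699	0.2039	0.2067	1.3815	4.6943	12.7105	32.4726
F	0.1083	0.3175	0.6487	0.5846	0.1421	0.2057	1.3439	4.2788	11.3932	28.7881
Na	0.2142	0.6853	0.7692	1.6589	1.4482	0.3334	2.3446	10.083	48.3037	138.27
Mg	0.2314	0.6866	0.9677	2.1882	1.1339	0.3278	2.272	10.9241	39.2898	101.975
P	0.2548	0.6106	1.4541	2.3204	0.8477	0.2908	1.874	8.5176	24.3434	63.2996
S	0.2497	0.5628	1.3899	2.1865	0.7715	0.2681	1.6711	7.0267	19.5377	50.3888
Cl	0.2443	0.5397	1.3919	2.0197	0.6621	0.2468	1.5242	6.1537	16.6687	42.3086
K	0.4115	1.4031	2.2784	2.6742	2.2162	0.3703	3.3874	13.1029	68.9592	194.433
Ca	0.4054	1.388	2.1602	3.7532	2.2063	0.3499	3.0991	11.9608	53.9353	142.389
Mn	0.3796	1.2094	1.7815	2.542	1.5937	0.2699	2.0455	7.4726	31.0604	91.5622
Fe	0.3946	1.2725	1.7031	2.314	1.4795	0.2717	2.0443	7.6007	29.9714	86.2265
Zn	0.4288	1.2646	1.4472	1.8294	1.0934	0.2593	1.7998	6.75	25.586	73.5284
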