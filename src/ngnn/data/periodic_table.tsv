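symbol	covalent_radius	electronegativity	atomic_number	atomic_mass	first_ionization_energy	electron_affinity
H	0.31	2.20	1	1.008	13.598	0.754
B	0.84	2.04	5	10.811	8.298	0.277
C	0.76	2.55	6	12.011	11.260	1.263
N	0.71	3.04	7	14.007	14.534	-0.070
O	0.66	3.44	8	15.999	13.618	1.461
F	0.57	3.98	9	18.998	17.423	3.401
Si	1.11	1.90	14	28.086	8.152	1.390
P	1.07	2.19	15	30.974	10.487	0.746
S	1.05	2.58	16	32.067	10.360	2.077
Cl	1.02	3.16	17	35.453	12.968	3.613
Ge	1.20	2.01	32	72.630	7.900	1.233
Se	1.20	2.55	34	78.971	9.752	2.021
Br	1.20	2.96	35	79.904	11.814	3.364
Sn	1.39	1.96	50	118.710	7.344	1.112
Te	1.38	2.10	52	127.600	9.010	1.971
I	1.39	2.66	53	126.904	10.451	3.059
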