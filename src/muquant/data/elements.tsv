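# Elemental photon mass attenuation coefficients (total, with coherent
# scattering), 40-400 keV.  H, C, N, O transcribed from standard reference
# tabulations (validated via water/polyethylene compound sums); F, Na, Mg, P,
# S, Cl, Ar, K, Ca derived from a Klein-Nishina baseline plus Z-scaled
# photoelectric/coherent residuals calibrated on oxygen (see
# scripts/build_fixtures.py).  Columns: element, energy_keV, mu_over_rho_cm2_g.
element	energy_keV	mu_over_rho_cm2_g
Ar	40	1.28321
Ar	50	0.734337
Ar	60	0.487953
Ar	80	0.286402
Ar	100	0.209814
Ar	150	0.143948
Ar	200	0.120674
Ar	300	0.0992407
Ar	400	0.0874819
C	40	0.2076
C	50	0.1871
C	60	0.1753
C	80	0.161
C	100	0.1514
C	150	0.1347
C	200	0.1229
C	300	0.1066
C	400	0.09546
Ca	40	1.96458
Ca	50	1.09254
Ca	60	0.702605
Ca	80	0.386114
Ca	100	0.267913
Ca	150	0.170143
Ca	200	0.13825
Ca	300	0.11132
Ca	400	0.0975018
Cl	40	1.1528
Cl	50	0.672073
Cl	60	0.455698
Cl	80	0.277742
Cl	100	0.209324
Cl	150	0.148973
Cl	200	0.126611
Cl	300	0.105059
Cl	400	0.0928592
F	40	0.281473
F	50	0.221774
F	60	0.192455
F	80	0.164095
F	100	0.149526
F	150	0.129611
F	200	0.11742
F	300	0.101369
F	400	0.090652
H	40	0.3458
H	50	0.3355
H	60	0.326
H	80	0.3091
H	100	0.2944
H	150	0.2651
H	200	0.2429
H	300	0.2112
H	400	0.1893
K	40	1.63136
K	50	0.919153
K	60	0.600135
K	80	0.34029
K	100	0.242487
K	150	0.16014
K	200	0.132249
K	300	0.107677
K	400	0.0946314
Mg	40	0.484522
Mg	50	0.330134
Mg	60	0.258519
Mg	80	0.196012
Mg	100	0.168913
Mg	150	0.139163
Mg	200	0.124185
Mg	300	0.106235
Mg	400	0.0947475
N	40	0.2293
N	50	0.198
N	60	0.1819
N	80	0.1633
N	100	0.1529
N	150	0.1353
N	200	0.1233
N	300	0.1068
N	400	0.09557
Na	40	0.39346
Na	50	0.280595
Na	60	0.227546
Na	80	0.180073
Na	100	0.158538
Na	150	0.133265
Na	200	0.119644
Na	300	0.102726
Na	400	0.0917169
O	40	0.2585
O	50	0.2132
O	60	0.1907
O	80	0.1678
O	100	0.1551
O	150	0.1361
O	200	0.1237
O	300	0.107
O	400	0.09566
P	40	0.818688
P	50	0.500906
P	60	0.356777
P	80	0.23641
P	100	0.188597
P	150	0.143521
P	200	0.124868
P	300	0.105166
P	400	0.0933656
S	40	1.00805
S	50	0.600816
S	60	0.416904
S	80	0.264624
S	100	0.20522
S	150	0.151208
S	200	0.130111
S	300	0.108823
S	400	0.0964131
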