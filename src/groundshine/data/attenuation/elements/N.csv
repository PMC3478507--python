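# Photon interaction data, element N
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,3.44747,0.192754,0
0.011015,2.52023,0.192037,0
0.012133,1.84239,0.191256,0
0.013365,1.34669,0.190405,0
0.014721,0.984601,0.189479,0
0.016215,0.717336,0.188473,0
0.017861,0.522149,0.187381,0
0.019674,0.380079,0.186198,0
0.021671,0.27563,0.184917,0
0.023871,0.199724,0.183533,0
0.026294,0.144728,0.182041,0
0.028963,0.104874,0.180434,0
0.031902,0.0758367,0.178708,0
0.03514,0.0547663,0.176857,0
0.038707,0.0395489,0.174878,0
0.042636,0.0285069,0.172766,0
0.046964,0.0205279,0.170519,0
0.051731,0.0147484,0.168134,0
0.056981,0.0105517,0.165612,0
0.062765,0.00760473,0.162951,0
0.069136,0.00552749,0.160154,0
0.076153,0.00401776,0.157224,0
0.083883,0.0029203,0.154165,0
0.092397,0.00212266,0.150984,0
0.101775,0.00154289,0.147688,0
0.112106,0.00112144,0.144285,0
0.123485,0.000815126,0.140787,0
0.136018,0.000592493,0.137205,0
0.149825,0.000430649,0.13355,0
0.165032,0.000313023,0.129837,0
0.181783,0.000227523,0.126078,0
0.200234,0.000165378,0.122288,0
0.220558,0.000120206,0.118478,0
0.242945,8.73726e-05,0.114662,0
0.267605,6.35069e-05,0.110853,0
0.294767,4.61606e-05,0.107061,0
0.324686,3.35523e-05,0.103296,0
0.357642,2.43877e-05,0.0995679,0
0.393944,1.77263e-05,0.0958837,0
0.433929,1.28846e-05,0.0922504,0
0.477974,9.36521e-06,0.0886731,0
0.526489,6.80717e-06,0.0851565,0
0.579929,4.94783e-06,0.0817042,0
0.638792,3.59638e-06,0.0783192,0
0.703631,2.61405e-06,0.0750038,0
0.77505,1.90004e-06,0.07176,0
0.853719,1.38106e-06,0.0685894,0
0.940373,1.00383e-06,0.0654936,0
1.03582,7.29643e-07,0.062474,1.77005e-09
1.14096,5.30347e-07,0.0595319,1.92065e-06
1.25677,3.85486e-07,0.0566686,1.3948e-05
1.38433,2.80194e-07,0.0538855,4.3908e-05
1.52484,2.03661e-07,0.0511837,9.63169e-05
1.67962,1.48032e-07,0.0485646,0.000172659
1.8501,1.07598e-07,0.0460292,0.000272153
2.03789,7.82087e-08,0.0435786,0.000392516
2.24474,5.68466e-08,0.0412136,0.000530595
2.47258,4.13193e-08,0.0389348,0.000682848
2.72356,3.00332e-08,0.0367427,0.000845678
3,2.18299e-08,0.0346375,0.00101566
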