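# Photon interaction data, element Ar
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,61.5851,0.173791,0
0.011015,46.4582,0.173145,0
0.012133,35.0471,0.172441,0
0.013365,26.4357,0.171673,0
0.014721,19.9446,0.170839,0
0.016215,15.0499,0.169932,0
0.017861,11.3564,0.168947,0
0.019674,8.5695,0.16788,0
0.021671,6.40744,0.166725,0
0.023871,4.78169,0.165478,0
0.026294,3.56858,0.164132,0
0.028963,2.66322,0.162683,0
0.031902,1.98213,0.161127,0
0.03514,1.47274,0.159458,0
0.038707,1.09423,0.157674,0
0.042636,0.811746,0.15577,0
0.046964,0.601696,0.153743,0
0.051731,0.445787,0.151593,0
0.056981,0.329989,0.149319,0
0.062765,0.244132,0.14692,0
0.069136,0.180509,0.144398,0
0.076153,0.133471,0.141757,0
0.083883,0.097467,0.138999,0
0.092397,0.0702623,0.13613,0
0.101775,0.051106,0.133159,0
0.112106,0.0386952,0.130091,0
0.123485,0.0292988,0.126937,0
0.136018,0.0221845,0.123707,0
0.149825,0.0167971,0.120412,0
0.165032,0.012396,0.117064,0
0.181783,0.00914512,0.113675,0
0.200234,0.00674681,0.110257,0
0.220558,0.00497744,0.106822,0
0.242945,0.00367209,0.103382,0
0.267605,0.00270905,0.0999473,0
0.294767,0.0019986,0.0965283,0
0.324686,0.00147446,0.0931341,0
0.357642,0.00108778,0.0897726,0
0.393944,0.000802502,0.0864509,0
0.433929,0.000592047,0.083175,0
0.477974,0.000436779,0.0799496,0
0.526489,0.000322233,0.076779,0
0.579929,0.000237725,0.0736663,0
0.638792,0.000175382,0.0706143,0
0.703631,0.000129387,0.067625,0
0.77505,9.5455e-05,0.0647004,0
0.853719,7.04215e-05,0.0618417,0
0.940373,5.19532e-05,0.0590505,0
1.03582,3.83283e-05,0.0563279,3.7903e-09
1.14096,2.82767e-05,0.0536753,4.11279e-06
1.25677,2.0861e-05,0.0510937,2.98676e-05
1.38433,1.53901e-05,0.0485843,9.40226e-05
1.52484,1.1354e-05,0.0461484,0.000206248
1.67962,8.37639e-06,0.0437869,0.000369724
1.8501,6.17965e-06,0.041501,0.000582775
2.03789,4.55902e-06,0.0392915,0.000840514
2.24474,3.3634e-06,0.0371591,0.00113619
2.47258,2.48133e-06,0.0351045,0.00146222
2.72356,1.8306e-06,0.0331281,0.00181089
3,1.35052e-06,0.0312299,0.00217489
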