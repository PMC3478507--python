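# Photon interaction data, element Si
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,33.0131,0.192266,0
0.011015,24.7096,0.191552,0
0.012133,18.4947,0.190772,0
0.013365,13.8413,0.189923,0
0.014721,10.3611,0.189,0
0.016215,7.71736,0.187997,0
0.017861,5.74104,0.186908,0
0.019674,4.2709,0.185727,0
0.021671,3.16566,0.18445,0
0.023871,2.3446,0.183069,0
0.026294,1.73656,0.18158,0
0.028963,1.2862,0.179978,0
0.031902,0.950799,0.178256,0
0.03514,0.701997,0.17641,0
0.038707,0.518286,0.174436,0
0.042636,0.382139,0.172329,0
0.046964,0.281557,0.170087,0
0.051731,0.207392,0.167709,0
0.056981,0.152686,0.165193,0
0.062765,0.112382,0.162539,0
0.069136,0.0827006,0.159749,0
0.076153,0.06086,0.156826,0
0.083883,0.0447855,0.153775,0
0.092397,0.0329571,0.150602,0
0.101775,0.0242696,0.147314,0
0.112106,0.017927,0.143921,0
0.123485,0.0132422,0.140431,0
0.136018,0.0097819,0.136858,0
0.149825,0.0072255,0.133213,0
0.165032,0.00533735,0.129509,0
0.181783,0.00394257,0.12576,0
0.200234,0.00291229,0.121978,0
0.220558,0.00215124,0.118178,0
0.242945,0.00158906,0.114372,0
0.267605,0.00117379,0.110573,0
0.294767,0.000867055,0.10679,0
0.324686,0.000640474,0.103035,0
0.357642,0.000473102,0.0993162,0
0.393944,0.000349467,0.0956413,0
0.433929,0.000258144,0.0920171,0
0.477974,0.000190684,0.0884489,0
0.526489,0.000140854,0.0849412,0
0.579929,0.000104045,0.0814976,0
0.638792,7.68556e-05,0.0781212,0
0.703631,5.67711e-05,0.0748141,0
0.77505,4.19355e-05,0.0715785,0
0.853719,3.09767e-05,0.068416,0
0.940373,2.28817e-05,0.065328,0
1.03582,1.69022e-05,0.062316,3.31045e-09
1.14096,1.24852e-05,0.0593814,3.59212e-06
1.25677,9.22251e-06,0.0565253,2.60864e-05
1.38433,6.81246e-06,0.0537492,8.21194e-05
1.52484,5.03219e-06,0.0510543,0.000180138
1.67962,3.71715e-06,0.0484418,0.000322917
1.8501,2.74577e-06,0.0459129,0.000508997
2.03789,2.02823e-06,0.0434685,0.000734106
2.24474,1.4982e-06,0.0411094,0.00099235
2.47258,1.10669e-06,0.0388364,0.0012771
2.72356,8.17481e-07,0.0366498,0.00158164
3,6.03853e-07,0.0345499,0.00189955
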