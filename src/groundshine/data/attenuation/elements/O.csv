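# Photon interaction data, element O
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,5.46578,0.192862,0
0.011015,4.01442,0.192145,0
0.012133,2.94847,0.191363,0
0.013365,2.16528,0.190512,0
0.014721,1.59051,0.189586,0
0.016215,1.16403,0.188579,0
0.017861,0.851103,0.187487,0
0.019674,0.622312,0.186303,0
0.021671,0.453627,0.185021,0
0.023871,0.330445,0.183636,0
0.026294,0.240723,0.182143,0
0.028963,0.175361,0.180535,0
0.031902,0.127481,0.178808,0
0.03514,0.0925519,0.176957,0
0.038707,0.0671913,0.174976,0
0.042636,0.0487033,0.172863,0
0.046964,0.0352732,0.170614,0
0.051731,0.0255475,0.168229,0
0.056981,0.0185048,0.165705,0
0.062765,0.0133828,0.163043,0
0.069136,0.00966203,0.160244,0
0.076153,0.00697596,0.157312,0
0.083883,0.0050531,0.154252,0
0.092397,0.00367291,0.151069,0
0.101775,0.00266972,0.147771,0
0.112106,0.00194047,0.144366,0
0.123485,0.00141044,0.140866,0
0.136018,0.00102521,0.137282,0
0.149825,0.000745167,0.133626,0
0.165032,0.000541635,0.12991,0
0.181783,0.000393691,0.126149,0
0.200234,0.000286159,0.122356,0
0.220558,0.000207997,0.118545,0
0.242945,0.000151184,0.114727,0
0.267605,0.000109888,0.110915,0
0.294767,7.98733e-05,0.107121,0
0.324686,5.80566e-05,0.103354,0
0.357642,4.21989e-05,0.0996239,0
0.393944,3.06724e-05,0.0959376,0
0.433929,2.22946e-05,0.0923022,0
0.477974,1.62049e-05,0.0887229,0
0.526489,1.17787e-05,0.0852044,0
0.579929,8.5614e-06,0.0817502,0
0.638792,6.22294e-06,0.0783633,0
0.703631,4.52317e-06,0.0750459,0
0.77505,3.28771e-06,0.0718003,0
0.853719,2.38969e-06,0.068628,0
0.940373,1.73697e-06,0.0655304,0
1.03582,1.26253e-06,0.0625091,1.99243e-09
1.14096,9.17678e-07,0.0595654,2.16195e-06
1.25677,6.6702e-07,0.0567005,1.57004e-05
1.38433,4.84829e-07,0.0539158,4.94243e-05
1.52484,3.52402e-07,0.0512125,0.000108417
1.67962,2.56146e-07,0.0485919,0.000194351
1.8501,1.86181e-07,0.0460551,0.000306344
2.03789,1.35327e-07,0.0436031,0.000441828
2.24474,9.83636e-08,0.0412368,0.000597255
2.47258,7.14962e-08,0.0389567,0.000768636
2.72356,5.19676e-08,0.0367634,0.000951923
3,3.7773e-08,0.0346569,0.00114326
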