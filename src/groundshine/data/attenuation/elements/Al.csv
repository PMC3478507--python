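# Photon interaction data, element Al
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,25.4524,0.185831,0
0.011015,18.9986,0.185141,0
0.012133,14.1814,0.184387,0
0.013365,10.5844,0.183567,0
0.014721,7.90147,0.182675,0
0.016215,5.8717,0.181705,0
0.017861,4.35834,0.180652,0
0.019674,3.23508,0.179511,0
0.021671,2.39307,0.178276,0
0.023871,1.7689,0.176942,0
0.026294,1.30759,0.175503,0
0.028963,0.96657,0.173954,0
0.031902,0.713216,0.17229,0
0.03514,0.525669,0.170506,0
0.038707,0.387429,0.168597,0
0.042636,0.285156,0.166561,0
0.046964,0.209732,0.164395,0
0.051731,0.154226,0.162096,0
0.056981,0.113368,0.159664,0
0.062765,0.0833332,0.157099,0
0.069136,0.0612597,0.154402,0
0.076153,0.0450343,0.151578,0
0.083883,0.0331128,0.148629,0
0.092397,0.0243532,0.145562,0
0.101775,0.0179229,0.142384,0
0.112106,0.0132298,0.139104,0
0.123485,0.00976573,0.135731,0
0.136018,0.00720886,0.132278,0
0.149825,0.00532121,0.128754,0
0.165032,0.00392795,0.125174,0
0.181783,0.00289947,0.121551,0
0.200234,0.00214029,0.117896,0
0.220558,0.00157988,0.114223,0
0.242945,0.00116621,0.110544,0
0.267605,0.000860848,0.106872,0
0.294767,0.000635448,0.103216,0
0.324686,0.000469066,0.0995865,0
0.357642,0.000346247,0.0959921,0
0.393944,0.000255585,0.0924402,0
0.433929,0.000188665,0.0889374,0
0.477974,0.000139265,0.0854886,0
0.526489,0.0001028,0.0820983,0
0.579929,7.58832e-05,0.07877,0
0.638792,5.60144e-05,0.0755065,0
0.703631,4.13476e-05,0.0723102,0
0.77505,3.05214e-05,0.0691828,0
0.853719,2.25297e-05,0.0661261,0
0.940373,1.66306e-05,0.0631415,0
1.03582,1.22761e-05,0.0602304,2.98634e-09
1.14096,9.06179e-06,0.0573939,3.24043e-06
1.25677,6.68906e-06,0.0546335,2.35324e-05
1.38433,4.93763e-06,0.0519503,7.40796e-05
1.52484,3.64477e-06,0.0493456,0.000162501
1.67962,2.69044e-06,0.0468205,0.000291302
1.8501,1.98598e-06,0.0443762,0.000459164
2.03789,1.46598e-06,0.0420136,0.000662234
2.24474,1.08213e-06,0.0397335,0.000895194
2.47258,7.98789e-07,0.0375366,0.00115207
2.72356,5.89637e-07,0.0354232,0.00142679
3,4.35248e-07,0.0333935,0.00171357
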