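# Photon interaction data, element Fe
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,168.821,0.179572,0
0.011015,129.785,0.178905,0
0.012133,99.7765,0.178177,0
0.013365,76.698,0.177384,0
0.014721,58.9696,0.176522,0
0.016215,45.0194,0.175584,0
0.017861,34.3093,0.174567,0
0.019674,26.1474,0.173465,0
0.021671,19.8049,0.172272,0
0.023871,14.9815,0.170982,0
0.026294,11.3332,0.169592,0
0.028963,8.57329,0.168095,0
0.031902,6.45989,0.166487,0
0.03514,4.85591,0.164763,0
0.038707,3.6501,0.162919,0
0.042636,2.73717,0.160951,0
0.046964,2.05001,0.158858,0
0.051731,1.53416,0.156636,0
0.056981,1.14645,0.154286,0
0.062765,0.855868,0.151807,0
0.069136,0.638255,0.149202,0
0.076153,0.475986,0.146472,0
0.083883,0.354731,0.143622,0
0.092397,0.264193,0.140659,0
0.101775,0.196778,0.137588,0
0.112106,0.146612,0.134418,0
0.123485,0.109237,0.131159,0
0.136018,0.0813917,0.127822,0
0.149825,0.0606418,0.124418,0
0.165032,0.0453747,0.120958,0
0.181783,0.0339527,0.117456,0
0.200234,0.0254092,0.113925,0
0.220558,0.0192115,0.110376,0
0.242945,0.0145255,0.106821,0
0.267605,0.0109824,0.103272,0
0.294767,0.00830361,0.0997393,0
0.324686,0.00627823,0.0962322,0
0.357642,0.00474687,0.0927589,0
0.393944,0.00358901,0.0893266,0
0.433929,0.0027136,0.0859417,0
0.477974,0.0020517,0.0826091,0
0.526489,0.00155126,0.079333,0
0.579929,0.00117288,0.0761168,0
0.638792,0.000886793,0.0729633,0
0.703631,0.000670487,0.0698746,0
0.77505,0.000506945,0.0668526,0
0.853719,0.000383292,0.0638988,0
0.940373,0.0002898,0.0610148,0
1.03582,0.000219113,0.0582016,5.56539e-09
1.14096,0.000165668,0.0554608,6.03891e-06
1.25677,0.000125259,0.0527933,4.38554e-05
1.38433,9.4706e-05,0.0502005,0.000138056
1.52484,7.16055e-05,0.0476835,0.000302839
1.67962,5.41397e-05,0.0452435,0.000542874
1.8501,4.09341e-05,0.0428815,0.000855703
2.03789,3.09496e-05,0.0405985,0.00123415
2.24474,2.34004e-05,0.0383952,0.0016683
2.47258,1.76927e-05,0.0362722,0.00214701
2.72356,1.33771e-05,0.0342301,0.00265898
3,1.01142e-05,0.0322688,0.00319344
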