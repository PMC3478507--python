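# Photon interaction data, element H
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,0.00748824,0.382639,0
0.011015,0.00549984,0.381217,0
0.012133,0.00403946,0.379666,0
0.013365,0.00296649,0.377976,0
0.014721,0.00217904,0.376139,0
0.016215,0.00159474,0.374142,0
0.017861,0.00116603,0.371974,0
0.019674,0.00085258,0.369625,0
0.021671,0.000621479,0.367083,0
0.023871,0.000452717,0.364335,0
0.026294,0.000329795,0.361372,0
0.028963,0.000240248,0.358183,0
0.031902,0.000174652,0.354757,0
0.03514,0.000126798,0.351083,0
0.038707,9.20535e-05,0.347153,0
0.042636,6.67246e-05,0.342961,0
0.046964,4.83251e-05,0.3385,0
0.051731,3.50006e-05,0.333766,0
0.056981,2.5352e-05,0.328759,0
0.062765,1.83347e-05,0.323477,0
0.069136,1.32372e-05,0.317924,0
0.076153,9.55721e-06,0.312108,0
0.083883,6.92285e-06,0.306036,0
0.092397,5.03197e-06,0.299721,0
0.101775,3.65758e-06,0.293178,0
0.112106,2.65848e-06,0.286423,0
0.123485,1.93233e-06,0.279479,0
0.136018,1.40456e-06,0.272368,0
0.149825,1.02089e-06,0.265114,0
0.165032,7.42052e-07,0.257742,0
0.181783,5.39366e-07,0.250281,0
0.200234,3.92043e-07,0.242755,0
0.220558,2.8496e-07,0.235193,0
0.242945,2.07125e-07,0.227618,0
0.267605,1.50549e-07,0.220056,0
0.294767,1.09428e-07,0.212528,0
0.324686,7.95388e-08,0.205055,0
0.357642,5.78135e-08,0.197654,0
0.393944,4.20219e-08,0.190341,0
0.433929,3.05441e-08,0.183128,0
0.477974,2.22011e-08,0.176027,0
0.526489,1.61371e-08,0.169046,0
0.579929,1.17293e-08,0.162193,0
0.638792,8.52556e-09,0.155473,0
0.703631,6.19685e-09,0.148891,0
0.77505,4.50423e-09,0.142452,0
0.853719,3.27393e-09,0.136158,0
0.940373,2.37968e-09,0.130013,0
1.03582,1.72969e-09,0.124018,8.7844e-10
1.14096,1.25724e-09,0.118178,9.5318e-07
1.25677,9.13831e-10,0.112494,6.92212e-06
1.38433,6.64226e-10,0.106969,2.17907e-05
1.52484,4.82798e-10,0.101606,4.78001e-05
1.67962,3.50925e-10,0.0964065,8.56871e-05
1.8501,2.55072e-10,0.0913735,0.000135064
2.03789,1.85401e-10,0.0865088,0.000194798
2.24474,1.3476e-10,0.0818139,0.000263323
2.47258,9.79514e-11,0.0772903,0.000338884
2.72356,7.11967e-11,0.0729387,0.000419693
3,5.17498e-11,0.0687595,0.000504051
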