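# Photon interaction data, element C
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,tau_rho,sigma_incoh_rho,kappa_rho
0.01,1.99219,0.192674,0
0.011015,1.44879,0.191957,0
0.012133,1.05362,0.191176,0
0.013365,0.766133,0.190325,0
0.014721,0.557227,0.1894,0
0.016215,0.403716,0.188395,0
0.017861,0.292208,0.187303,0
0.019674,0.211502,0.18612,0
0.021671,0.0807894,0.18484,0
0.023871,0.0270697,0.183457,0
0.026294,0.00907142,0.181965,0
0.028963,0.00303989,0.180359,0
0.031902,0.000149775,0.178634,0
0.03514,2.46071e-06,0.176784,0
0.038707,4.04126e-08,0.174805,0
0.042636,4.97483e-07,0.172694,0
0.046964,0.000185049,0.170448,0
0.051731,0.00827881,0.168064,0
0.056981,0.00751603,0.165543,0
0.062765,0.0068234,0.162883,0
0.069136,0.00619461,0.160087,0
0.076153,0.00562382,0.157159,0
0.083883,0.00510557,0.154101,0
0.092397,0.00463512,0.150921,0
0.101775,0.00420802,0.147626,0
0.112106,0.00382023,0.144225,0
0.123485,0.0034682,0.140729,0
0.136018,0.00314863,0.137148,0
0.149825,0.00285847,0.133495,0
0.165032,0.00259508,0.129783,0
0.181783,0.00235595,0.126026,0
0.200234,0.00213885,0.122237,0
0.220558,0.00194176,0.118429,0
0.242945,0.00176283,0.114615,0
0.267605,0.00160038,0.110807,0
0.294767,0.00145291,0.107016,0
0.324686,0.00131903,0.103253,0
0.357642,0.00119748,0.0995264,0
0.393944,0.00108714,0.0958438,0
0.433929,0.000986961,0.0922119,0
0.477974,0.000896013,0.0886362,0
0.526489,0.000813447,0.0851211,0
0.579929,0.000738488,0.0816702,0
0.638792,0.000670439,0.0782866,0
0.703631,0.000608658,0.0749725,0
0.77505,0.000552572,0.0717301,0
0.853719,0.000501653,0.0685608,0
0.940373,0.000455427,0.0654663,0
1.03582,0.00041346,0.062448,1.54815e-09
1.14096,0.00037536,0.0595071,1.67987e-06
1.25677,0.000340771,0.056645,1.21994e-05
1.38433,0.00030937,0.053863,3.84035e-05
1.52484,0.000280862,0.0511624,8.42422e-05
1.67962,0.000254981,0.0485444,0.000151014
1.8501,0.000231485,0.0460101,0.000238035
2.03789,0.000210154,0.0435605,0.000343308
2.24474,0.000190789,0.0411965,0.000464077
2.47258,0.000173208,0.0389186,0.000597243
2.72356,0.000157247,0.0367274,0.00073966
3,0.000142757,0.034623,0.000888332
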