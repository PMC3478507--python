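# Photon interaction data, material air (components [('N2', 0.7552), ('O2', 0.232), ('Ar', 0.0128)], density 0.0012 g/cm3)
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,mu_rho,mu_en_rho,f_photo,f_compton,f_pair
0.01,4.85242,4.66349,0.960322,0.0396784,0
0.011015,3.62111,3.43324,0.947027,0.0529729,0
0.012133,2.71506,2.52833,0.929637,0.0703631,0
0.013365,2.04794,1.86245,0.907131,0.092869,0
0.014721,1.55713,1.37299,0.878452,0.121548,0
0.016215,1.19269,1.01001,0.842154,0.157846,0
0.017861,0.924315,0.743222,0.797504,0.202496,0
0.019674,0.727089,0.547705,0.744202,0.255798,0
0.021671,0.580121,0.402581,0.681604,0.318396,0
0.023871,0.472026,0.29647,0.611619,0.388381,0
0.026294,0.392659,0.219235,0.536913,0.463087,0
0.028963,0.334204,0.163064,0.460719,0.539281,0
0.031902,0.290725,0.122027,0.385996,0.614004,0
0.03514,0.25834,0.0922472,0.316182,0.683818,0
0.038707,0.234142,0.07082,0.253956,0.746044,0
0.042636,0.215789,0.0554049,0.200279,0.799721,0
0.046964,0.201714,0.0444365,0.155605,0.844395,0
0.051731,0.190715,0.0367115,0.119398,0.880602,0
0.056981,0.18191,0.0313437,0.090625,0.909375,0
0.062765,0.17474,0.0277702,0.0685178,0.931482,0
0.069136,0.1687,0.0254796,0.0517278,0.948272,0
0.076153,0.163408,0.0240805,0.0389276,0.961072,0
0.083883,0.158616,0.0233152,0.0291603,0.97084,0
0.092397,0.154168,0.0230121,0.0217588,0.978241,0
0.101775,0.14996,0.0230542,0.0162625,0.983737,0
0.112106,0.145915,0.0233486,0.0122839,0.987716,0
0.123485,0.141946,0.0237901,0.00928401,0.990716,0
0.136018,0.138019,0.0243258,0.00702265,0.992977,0
0.149825,0.134113,0.0249152,0.00531722,0.994683,0
0.165032,0.130211,0.0255233,0.00399906,0.996001,0
0.181783,0.126316,0.0261322,0.00301006,0.99699,0
0.200234,0.122427,0.0267229,0.00226781,0.997732,0
0.220558,0.118547,0.0272808,0.00171026,0.99829,0
0.242945,0.114681,0.0277948,0.00129107,0.998709,0
0.267605,0.110836,0.0282564,0.00097559,0.999024,0
0.294767,0.107019,0.0286595,0.000737937,0.999262,0
0.324686,0.103237,0.0289996,0.000558722,0.999441,0
0.357642,0.0994976,0.0292736,0.000423441,0.999577,0
0.393944,0.0958062,0.0294794,0.00032122,0.999679,0
0.433929,0.0921687,0.0296156,0.000243911,0.999756,0
0.477974,0.0885894,0.0296818,0.000185383,0.999815,0
0.526489,0.0850724,0.0296777,0.000141033,0.999859,0
0.579929,0.0816207,0.0296038,0.000107396,0.999893,0
0.638792,0.0782372,0.0294608,8.18612e-05,0.999918,0
0.703631,0.0749238,0.02925,6.24589e-05,0.999938,0
0.77505,0.0716824,0.0289729,4.77033e-05,0.999952,0
0.853719,0.0685145,0.0286315,3.64709e-05,0.999964,0
0.940373,0.0654215,0.0282283,2.79124e-05,0.999972,0
1.03582,0.0624048,0.0277661,2.13851e-05,0.999979,2.96051e-08
1.14096,0.0594677,0.0272485,1.64015e-05,0.99995,3.37106e-05
1.25677,0.0566199,0.0266814,1.25908e-05,0.99973,0.000257124
1.38433,0.053871,0.0260732,9.67267e-06,0.99914,0.000850723
1.52484,0.0512269,0.0254336,7.43542e-06,0.99803,0.00196247
1.67962,0.0486903,0.0247716,5.71855e-06,0.996293,0.00370123
1.8501,0.0462615,0.024095,4.40002e-06,0.993855,0.00614033
2.03789,0.0439393,0.0234104,3.38682e-06,0.990673,0.00932402
2.24474,0.041721,0.0227226,2.60786e-06,0.986723,0.0132742
2.47258,0.0396037,0.0220353,2.00872e-06,0.982002,0.0179965
2.72356,0.037584,0.0213516,1.54771e-06,0.976513,0.0234856
3,0.0356585,0.0206734,1.19287e-06,0.97027,0.0297293
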