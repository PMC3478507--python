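# Photon interaction data, material soil (components [('SiO2', 0.583), ('Al2O3', 0.167), ('Fe2O3', 0.083), ('H2O', 0.167)], density 1.0 g/cm3)
# energy range 0.01-3 MeV, log-spaced grid; coherent scattering excluded.
# Photoelectric components extracted from total mass-attenuation anchor
# values of the standard published compilation for elements by subtracting
# the analytic free-electron Klein-Nishina incoherent term and a screened-
# Rayleigh estimate; pair production from a near-threshold parameterisation
# calibrated on the air pair component at 2-3 MeV.  Regenerate with
# tools/build_attenuation_tables.py.
energy_MeV,mu_rho,mu_en_rho,f_photo,f_compton,f_pair
0.01,24.3155,24.1243,0.991986,0.00801356,0
0.011015,18.3991,18.209,0.989449,0.010551,0
0.012133,13.9373,13.7484,0.986128,0.013872,0
0.013365,10.5702,10.3825,0.98179,0.0182095,0
0.014721,8.03131,7.84495,0.97615,0.0238496,0
0.016215,6.08073,5.89586,0.968667,0.0313328,0
0.017861,4.60956,4.42629,0.958907,0.0410934,0
0.019674,3.50596,3.32441,0.946312,0.0536876,0
0.021671,2.66598,2.48631,0.929883,0.0701173,0
0.023871,2.03637,1.8587,0.908891,0.0911093,0
0.026294,1.56614,1.39063,0.882498,0.117502,0
0.028963,1.21466,1.04146,0.849836,0.150164,0
0.031902,0.949508,0.77878,0.809739,0.190261,0
0.03514,0.7505,0.582407,0.76178,0.23822,0
0.038707,0.601953,0.436665,0.706318,0.293682,0
0.042636,0.490281,0.327966,0.64378,0.35622,0
0.046964,0.406488,0.247318,0.575938,0.424062,0
0.051731,0.343544,0.187687,0.505258,0.494742,0
0.056981,0.296006,0.143628,0.434419,0.565581,0
0.062765,0.259929,0.111191,0.366266,0.633734,0
0.069136,0.232336,0.0873928,0.303172,0.696828,0
0.076153,0.211058,0.0700539,0.246952,0.753048,0
0.083883,0.194411,0.0574812,0.198376,0.801624,0
0.092397,0.181165,0.0484308,0.157517,0.842483,0
0.101775,0.17042,0.0419866,0.123947,0.876053,0
0.112106,0.161514,0.0374729,0.0969404,0.90306,0
0.123485,0.153927,0.0343494,0.075403,0.924597,0
0.136018,0.147304,0.0322421,0.0584129,0.941587,0
0.149825,0.141384,0.0308723,0.0451173,0.954883,0
0.165032,0.135992,0.0300439,0.0348581,0.965142,0
0.181783,0.130975,0.0295851,0.0268993,0.973101,0
0.200234,0.126239,0.0293824,0.020745,0.979255,0
0.220558,0.121727,0.0293621,0.0160864,0.983914,0
0.242945,0.117376,0.0294438,0.0124761,0.987524,0
0.267605,0.113156,0.0295824,0.00967976,0.99032,0
0.294767,0.109046,0.0297439,0.00751439,0.992486,0
0.324686,0.105035,0.0299034,0.00583729,0.994163,0
0.357642,0.101111,0.0300421,0.00453789,0.995462,0
0.393944,0.0972716,0.0301464,0.0035306,0.996469,0
0.433929,0.0935124,0.0302064,0.0027493,0.997251,0
0.477974,0.0898315,0.0302149,0.00214283,0.997857,0
0.526489,0.0862283,0.0301669,0.00167172,0.998328,0
0.579929,0.0827022,0.0300592,0.00130546,0.998695,0
0.638792,0.0792533,0.0298898,0.00102047,0.99898,0
0.703631,0.0758814,0.0296579,0.000798522,0.999201,0
0.77505,0.0725871,0.0293635,0.000625515,0.999374,0
0.853719,0.0693706,0.0290076,0.000490526,0.999509,0
0.940373,0.0662325,0.0285917,0.000385099,0.999615,0
1.03582,0.0631737,0.0281181,0.000302678,0.999697,4.15689e-08
1.14096,0.0601976,0.0275899,0.000238165,0.999714,4.73357e-05
1.25677,0.0573174,0.0270137,0.000187574,0.999451,0.000361032
1.38433,0.0545457,0.0263995,0.000147831,0.998658,0.00119427
1.52484,0.0518902,0.0257589,0.000116565,0.99713,0.00275382
1.67962,0.0493543,0.0251028,9.19431e-05,0.994718,0.00519018
1.8501,0.0469378,0.0244403,7.25394e-05,0.991325,0.00860219
2.03789,0.0446382,0.0237782,5.72404e-05,0.986897,0.0130457
2.24474,0.0424517,0.0231213,4.51739e-05,0.981412,0.0185433
2.47258,0.0403735,0.0224731,3.56548e-05,0.974872,0.0250927
2.72356,0.0383987,0.0218353,2.81441e-05,0.967297,0.0326744
3,0.0365224,0.0212092,2.22173e-05,0.95872,0.0412579
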