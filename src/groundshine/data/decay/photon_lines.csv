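# Photon emission lines for selected ground-source nuclides.
# Approximate transcription of an ICRP-107-style decay-data compilation
# (energies in MeV, yields in photons per decay). X-ray multiplets are
# binned into single representative lines; yields rounded to 2-3 figures.
# Ba-137m is listed as its own nuclide (the Cs-137 daughter); choose the
# daughter spectrum explicitly when assessing Cs-137 deposits.
# Lines with yield below ~1e-4 are omitted.
nuclide,energy_MeV,yield_per_decay
Co-60,1.17323,0.9985
Co-60,1.33249,0.9998
Ba-137m,0.66166,0.898
Ba-137m,0.0322,0.0568
Ba-137m,0.0364,0.0132
Cs-134,0.56325,0.0835
Cs-134,0.56914,0.1538
Cs-134,0.60472,0.9762
Cs-134,0.79586,0.8546
Cs-134,0.80193,0.0872
Cs-134,1.03860,0.0099
Cs-134,1.16796,0.0179
Cs-134,1.36516,0.0303
Cs-134,0.47536,0.0148
Am-241,0.05954,0.359
Am-241,0.02634,0.024
Am-241,0.0139,0.130
Am-241,0.0177,0.193
Am-241,0.0210,0.049
Sm-151,0.0056,0.0045
Sm-151,0.0061,0.0050
Sm-151,0.0070,0.0016
Bi-214,0.60932,0.4549
Bi-214,0.66845,0.0046
Bi-214,0.76836,0.0489
Bi-214,0.80617,0.0122
Bi-214,0.93406,0.0310
Bi-214,1.12028,0.1492
Bi-214,1.15521,0.0163
Bi-214,1.23811,0.0583
Bi-214,1.28097,0.0143
Bi-214,1.37767,0.0392
Bi-214,1.40174,0.0133
Bi-214,1.40798,0.0239
Bi-214,1.50920,0.0212
Bi-214,1.66128,0.0112
Bi-214,1.72960,0.0283
Bi-214,1.76449,0.1531
Bi-214,1.84742,0.0202
Bi-214,2.11855,0.0114
Bi-214,2.20421,0.0489
Bi-214,2.44786,0.0155
Ce-141,0.14544,0.482
Ce-141,0.0358,0.0475
Ce-141,0.0404,0.0100
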