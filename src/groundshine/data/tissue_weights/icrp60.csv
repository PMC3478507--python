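# Tissue weighting factors w_T of ICRP Publication 60 (1990 recommendations).
# Sum of weights = 1. The remainder weight (0.05) is applied to the
# arithmetic mean of the remainder tissues available for each sex
# (simplification: ICRP 60's mass-weighted rule and its splitting rule for a
# single dominant remainder organ are replaced by an unweighted mean; this
# is flagged in the scheme metadata).
kind,tissue,value,sex
weight,gonads,0.20,both
weight,red_bone_marrow,0.12,both
weight,colon,0.12,both
weight,lung,0.12,both
weight,stomach,0.12,both
weight,bladder,0.05,both
weight,breast,0.05,both
weight,liver,0.05,both
weight,oesophagus,0.05,both
weight,thyroid,0.05,both
weight,skin,0.01,both
weight,bone_surface,0.01,both
weight,remainder,0.05,both
member,adrenals,,both
member,brain,,both
member,upper_large_intestine,,both
member,small_intestine,,both
member,kidneys,,both
member,muscle,,both
member,pancreas,,both
member,spleen,,both
member,thymus,,both
member,uterus_cervix,,female
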