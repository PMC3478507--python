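# Tissue weighting factors w_T of ICRP Publication 103 (2007 recommendations).
# Sum of weights = 1. The remainder weight (0.12) is applied to the
# arithmetic mean of the 13 designated remainder tissues of each sex
# (simplification: the mass-weighted splitting rule is not applied; organ
# masses are phantom-specific and out of scope here).
kind,tissue,value,sex
weight,red_bone_marrow,0.12,both
weight,colon,0.12,both
weight,lung,0.12,both
weight,stomach,0.12,both
weight,breast,0.12,both
weight,remainder,0.12,both
weight,gonads,0.08,both
weight,bladder,0.04,both
weight,oesophagus,0.04,both
weight,liver,0.04,both
weight,thyroid,0.04,both
weight,bone_surface,0.01,both
weight,brain,0.01,both
weight,salivary_glands,0.01,both
weight,skin,0.01,both
member,adrenals,,both
member,extrathoracic_region,,both
member,gall_bladder,,both
member,heart,,both
member,kidneys,,both
member,lymphatic_nodes,,both
member,muscle,,both
member,oral_mucosa,,both
member,pancreas,,both
member,prostate,,male
member,uterus_cervix,,female
member,small_intestine,,both
member,spleen,,both
member,thymus,,both
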