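# Tissue composition table v1 (volume fractions per g tissue).
# Fractional water (f_water), neutral-lipid (f_neutral_lipid) and
# phospholipid (f_phospholipid) contents of mammalian tissues and plasma,
# as compiled in the tissue-composition partitioning literature
# (Poulin & Theil-type tables); used for both rat and human.
tissue,f_water,f_neutral_lipid,f_phospholipid
fat,0.180,0.790,0.0020
bone,0.439,0.074,0.0011
brain,0.770,0.051,0.0565
gut,0.718,0.0487,0.0163
heart,0.758,0.0115,0.0166
kidney,0.783,0.0207,0.0162
liver,0.751,0.0348,0.0252
lung,0.811,0.0030,0.0090
muscle,0.760,0.0238,0.0072
skin,0.718,0.0284,0.0111
spleen,0.788,0.0201,0.0198
rest,0.730,0.0400,0.0150
plasma,0.945,0.0023,0.0013
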