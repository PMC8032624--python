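# Default rat physiology (250 g Sprague-Dawley).
# Tissue volumes and blood flows follow standard reference compilations of
# rodent anatomy/perfusion (fractions of body weight and of cardiac output)
# widely used in generic whole-body kinetic models.  All values are
# user-overridable; the liver flow is the hepatic ARTERY flow only.
species_name: rat
body_weight: 0.25          # kg
cardiac_output: 5.38       # L/h
renal_clearance: 0.078     # L/h, glomerular filtration of unbound blood
tissue_volumes:            # L
  liver: 0.00915
  gut: 0.006725
  fat: 0.019025
  muscle: 0.101075
  skin: 0.047575
  bone: 0.01825
  brain: 0.001425
  heart: 0.000825
  kidney: 0.001825
  lung: 0.00125
  spleen: 0.0005
  venous_blood: 0.01235
  arterial_blood: 0.006175
  rest: 0.02385
blood_flows:               # L/h
  liver: 0.1130            # hepatic artery
  gut: 0.7048
  fat: 0.3766
  muscle: 1.4956
  skin: 0.3120
  bone: 0.6564
  brain: 0.1076
  heart: 0.2636
  kidney: 0.7586
  spleen: 0.0538
  rest: 0.5380
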