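# Default human physiology (70 kg adult).
# Tissue volumes and blood flows follow standard reference compilations of
# human anatomy/perfusion (fractions of body weight and of cardiac output)
# widely used in generic whole-body kinetic models.  All values are
# user-overridable; the liver flow is the hepatic ARTERY flow only (the
# portal inflow is gut + spleen effluent, assembled by the engine).
species_name: human
body_weight: 70.0          # kg
cardiac_output: 347.9      # L/h
renal_clearance: 6.7       # L/h, glomerular filtration of unbound blood
tissue_volumes:            # L
  liver: 1.80
  gut: 1.20
  fat: 15.00
  muscle: 28.00
  skin: 2.60
  bone: 6.00
  brain: 1.40
  heart: 0.33
  kidney: 0.31
  lung: 0.53
  spleen: 0.18
  venous_blood: 3.71
  arterial_blood: 1.85
  rest: 7.09
blood_flows:               # L/h
  liver: 22.61             # hepatic artery
  gut: 55.66
  fat: 17.40
  muscle: 59.14
  skin: 17.40
  bone: 17.40
  brain: 41.75
  heart: 13.92
  kidney: 66.10
  spleen: 10.44
  rest: 26.08
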