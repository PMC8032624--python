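# Profenofos physicochemical defaults.
# molecular_weight is the compound's formula weight.  logKow and fup are
# LITERATURE-SOURCED estimates (experimental logKow; fup from a
# lipophilicity-based plasma-binding estimate), not measured in-house:
# override them if better values are available.  Profenofos has no
# ionizable group near physiological pH and is treated as neutral.
name: profenofos
molecular_weight: 373.63   # g/mol
logKow: 4.44               # experimental octanol:water log partition coefficient
pKa: null
ionization: neutral
fup: 0.02                  # fraction unbound in plasma (estimated)
blood_plasma_ratio: 1.0    # default; predictions reported as blood concentrations
# kp_overrides:            # optional map tissue -> Kp, takes precedence over
#   liver: 2.5             # the tissue-composition estimate
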