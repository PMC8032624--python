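# 4-bromo-2-chlorophenol (BCP), the hydrolysis metabolite of profenofos.
# Properties are literature-style estimates for a halogenated phenol
# (weak acid, moderately lipophilic); override as needed.
name: bcp
molecular_weight: 207.46   # g/mol
logKow: 3.0
pKa: 8.0
ionization: acid
fup: 0.15
blood_plasma_ratio: 1.0
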