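# Measured in vitro Michaelis-Menten parameters for conversion of
# profenofos to BCP in liver microsomal, liver cytosolic and plasma
# incubations (Km in uM; Vmax in nmol/min/mg protein, or per mg plasma for
# the plasma matrix).  These feed the whole-body model after scaling.
human:
  liver_microsomes: {Km: 6.9, Vmax: 1.2}
  liver_cytosol: {Km: 1.4, Vmax: 1.1}
  plasma: {Km: 158.0, Vmax: 0.99}
rat:
  liver_microsomes: {Km: 8.1, Vmax: 8.9}
  liver_cytosol: {Km: 0.34, Vmax: 0.95}
  plasma: {Km: 3.6, Vmax: 0.68}
# Hepatic glucuronidation of BCP (rat evaluation sub-model).  Package
# defaults for phenol-type glucuronidation; user-overridable.
bcp_glucuronidation:
  Km: 300.0        # uM
  Vmax: 15.0       # nmol/min/mg microsomal protein
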