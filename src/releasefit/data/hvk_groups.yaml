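# Group-contribution table for Hoftyzer–Van Krevelen solubility parameters.
#
# fd, fp : molar attraction constants, (MJ/m^3)^(1/2) · cm^3 · mol^-1
#          (dispersion and polar components)
# eh     : hydrogen-bond cohesion energy, J · mol^-1
# vg     : Fedors molar-volume increment, cm^3 · mol^-1
#
# fd/fp/eh are the standard Hoftyzer–Van Krevelen molar attraction values;
# vg are Fedors group increments (the analysis reports no densities, so the
# molar volume is built by group addition).  Edit or override this file to
# use a different table edition.
version: 1
groups:
  "-CH3":      {fd: 420.0,  fp: 0.0,   eh: 0.0,     vg: 33.5}
  "-CH2-":     {fd: 270.0,  fp: 0.0,   eh: 0.0,     vg: 16.1}
  ">CH-":      {fd: 80.0,   fp: 0.0,   eh: 0.0,     vg: 1.0}
  "phenylene": {fd: 1270.0, fp: 110.0, eh: 0.0,     vg: 52.4}   # o/m/p-disubstituted aromatic ring (C6H4)
  "phenyl":    {fd: 1430.0, fp: 110.0, eh: 0.0,     vg: 71.4}   # monosubstituted aromatic ring (C6H5)
  "-OH":       {fd: 210.0,  fp: 500.0, eh: 20000.0, vg: 10.0}
  "-COOH":     {fd: 530.0,  fp: 420.0, eh: 10000.0, vg: 28.5}
  "-COO-":     {fd: 390.0,  fp: 490.0, eh: 7000.0,  vg: 18.0}   # ester
  "-NH2":      {fd: 280.0,  fp: 0.0,   eh: 8400.0,  vg: 19.2}
  "-O-":       {fd: 100.0,  fp: 400.0, eh: 3000.0,  vg: 3.8}    # ether
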