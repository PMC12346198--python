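# Compound registry for the niclosamide / valine-conjugate case studies.
#
# molar_mass values for the analogs are nominal configuration inputs (only
# niclosamide's free-acid mass is a literature constant).  Each valine
# conjugate's mass basis is the parent mass scaled by the dosed-form mass
# ratio implied by the study's molar-equivalent PO doses (e.g. 56.4/40 mg/kg
# = 1.41), so mg/kg <-> umol conversion reproduces those equivalences.
niclosamide:
  molar_mass: 327.12
  role: parent
compound_7:
  molar_mass: 350.12
  role: parent
compound_11:
  molar_mass: 315.67
  role: parent
valine_niclosamide:
  molar_mass: 461.24   # 327.12 x 1.41
  role: prodrug
  parent_name: niclosamide
valine_compound_7:
  molar_mass: 485.70   # 350.12 x 1.387 (55.49/40)
  role: prodrug
  parent_name: compound_7
valine_compound_11:
  molar_mass: 443.36   # 315.67 x 1.4045 (56.18/40)
  role: prodrug
  parent_name: compound_11
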