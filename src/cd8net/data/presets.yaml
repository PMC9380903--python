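# Scenario presets for the CD8+ T-cell network.
# Unlisted inputs default to 0 except IL15s, which defaults to 1
# (all conditions run in the presence of IL-15 unless stated).
ceramide:
  inputs:
    Ceramide: 1
  note: high systemic ceramides
diabetic:
  inputs:
    Ceramide: 1
    FFAs: 1
    Glucose: 1
  note: 'type-II-diabetes context: hyperglycemia + dyslipidemia + ceramides'
dyslipidemia:
  inputs:
    FFAs: 1
  note: high free fatty acids
ethanol:
  inputs:
    EtOH: 1
  note: chronic alcohol exposure
hyperglycemia:
  inputs:
    Glucose: 1
  note: high glucose
il12_ifng:
  inputs:
    IFNgs: 1
    IL12s: 1
    PD1: 1
  note: "IL-12 + IFN-\u03B3 pro-inflammatory polarization (PD-1 engaged)"
il4:
  inputs:
    IL4s: 1
  note: IL-4 Tc2 polarization
il4_il12:
  inputs:
    IL12s: 1
    IL4s: 1
  note: IL-4 + IL-12 regulatory polarization
il6_tgfb:
  inputs:
    IL6s: 1
    TGFb: 1
  note: "IL-6 + TGF-\u03B2 Tc17 polarization"
no_cytokines:
  inputs: {}
  note: baseline activated population, no polarizing cytokines
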