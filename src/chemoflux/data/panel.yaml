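# Measured metabolite panel for the chemostat labeling experiment:
# 28 intact metabolites quantified by HILIC-QTOF-HRMS, full carbon backbones,
# 164 mass isotopomer fractions in total. One measurement group (one scale
# factor) per metabolite. `pool` maps the measured species onto the model
# pool that carries its backbone (P5P is the summed pentose-phosphate pool,
# CIT the summed citrate/isocitrate pool).
panel:
  - {metabolite: G6P,  pool: G6P,  formula: C6H13O9P}
  - {metabolite: F6P,  pool: F6P,  formula: C6H13O9P}
  - {metabolite: FBP,  pool: FBP,  formula: C6H14O12P2}
  - {metabolite: DHAP, pool: DHAP, formula: C3H7O6P}
  - {metabolite: PGA,  pool: PGA,  formula: C3H7O7P}
  - {metabolite: PEP,  pool: PEP,  formula: C3H5O6P}
  - {metabolite: CIT,  pool: CIT,  formula: C6H8O7}
  - {metabolite: AKG,  pool: AKG,  formula: C5H6O5}
  - {metabolite: FUM,  pool: FUM,  formula: C4H4O4}
  - {metabolite: MAL,  pool: MAL,  formula: C4H6O5}
  - {metabolite: P5P,  pool: R5P,  formula: C5H11O8P}
  - {metabolite: S7P,  pool: S7P,  formula: C7H15O10P}
  - {metabolite: ALA,  pool: ALA,  formula: C3H7NO2}
  - {metabolite: VAL,  pool: VAL,  formula: C5H11NO2}
  - {metabolite: LEU,  pool: LEU,  formula: C6H13NO2}
  - {metabolite: ILE,  pool: ILE,  formula: C6H13NO2}
  - {metabolite: THR,  pool: THR,  formula: C4H9NO3}
  - {metabolite: MET,  pool: MET,  formula: C5H11NO2S}
  - {metabolite: ASP,  pool: ASP,  formula: C4H7NO4}
  - {metabolite: ASN,  pool: ASN,  formula: C4H8N2O3}
  - {metabolite: LYS,  pool: LYS,  formula: C6H14N2O2}
  - {metabolite: SER,  pool: SER,  formula: C3H7NO3}
  - {metabolite: GLY,  pool: GLY,  formula: C2H5NO2}
  - {metabolite: GLU,  pool: GLU,  formula: C5H9NO4}
  - {metabolite: GLN,  pool: GLN,  formula: C5H10N2O5}
  - {metabolite: ARG,  pool: ARG,  formula: C6H14N4O2}
  - {metabolite: PRO,  pool: PRO,  formula: C5H9NO2}
  - {metabolite: TYR,  pool: TYR,  formula: C9H11NO3}
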