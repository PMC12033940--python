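# Experimental cases: five networks (three secretome-based, two MS-based),
# each with a no-treatment baseline and interleukin stimulation conditions.
# Seeds are the baseline proteins of interest; stimuli are the cytokines
# added (and forced to the maximum score) under treatment conditions.
networks:
  trauma:
    dataset_kind: secretome
    phenotype: trauma
    seeds: [SERPINE1]
    conditions:
      baseline: []
      il4: [IL4]
      il1b: [IL1B]
  degenerated:
    dataset_kind: secretome
    phenotype: degenerated
    seeds: [MMP2]
    conditions:
      baseline: []
      il4: [IL4]
      il10: [IL10]
      il1b: [IL1B]
      il1b_il4: [IL1B, IL4]
      il1b_il10: [IL1B, IL10]
  explant:
    dataset_kind: secretome
    phenotype: explant
    seeds: [MMP2]
    conditions:
      baseline: []
      il4: [IL4]
      il1b: [IL1B]
      il10: [IL10]
      il1b_il4: [IL1B, IL4]
  young:
    dataset_kind: mass_spec
    phenotype: young
    seeds: &ms_seeds
      [CX3CL1, IL6ST, IL1B, IL6, CXCL8, IL18, IL16, GDF5, OSM, CXCL2,
       GDF6, IL17D, CCL3, IL20, TGFB1, CCL5, PMP2, LIF, CCL7, TNF,
       IGF1, CCL2, VEGFA, CXCL3, CXCL1]
    conditions:
      baseline: []
      il4: [IL4]
      il10: [IL10]
  old:
    dataset_kind: mass_spec
    phenotype: old
    seeds: *ms_seeds
    conditions:
      baseline: []
      il4: [IL4]
      il10: [IL10]
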