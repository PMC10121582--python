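# Base 2-HT model for two instruction conditions: the lineup-composition
# parameters b (biased suspect selection) and dA (culprit-absence detection)
# are equated across conditions because both conditions used the same
# lineups; dP and g remain free per condition. Six free parameters, df = 2.
lineup_size: 6
mode: paper
conditions: [FYC, noFYC]
restrictions:
  - "equal: b across [FYC, noFYC]"
  - "equal: dA across [FYC, noFYC]"
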