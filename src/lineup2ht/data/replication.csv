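# Response frequencies of the conceptual replication: 355 participants, four
# six-person lineups each (two culprit-present, two culprit-absent), randomly
# assigned to first-yes-counts instructions (FYC) or none (noFYC); 1420
# identification decisions total. Cell values cross-checked against the
# design: per condition the culprit-present and culprit-absent totals are
# equal (366/366 for FYC, 344/344 for noFYC) because every participant saw
# two lineups of each type.
condition,lineup_type,outcome,count
FYC,culprit_present,suspect,112
FYC,culprit_present,filler,147
FYC,culprit_present,rejection,107
FYC,culprit_absent,suspect,31
FYC,culprit_absent,filler,184
FYC,culprit_absent,rejection,151
noFYC,culprit_present,suspect,110
noFYC,culprit_present,filler,167
noFYC,culprit_present,rejection,67
noFYC,culprit_absent,suspect,50
noFYC,culprit_absent,filler,194
noFYC,culprit_absent,rejection,100
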