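# Response frequencies of the two sequential-lineup instruction conditions
# (first-yes-counts instructions, FYC, vs. none, noFYC), aggregated across
# suspect position; six-person lineups; 559 identification decisions total.
# Cell values cross-checked against two independent published facts: the
# condition totals (305 + 254 = 559) and the pooled lineup rejection rates
# (0.53 for FYC, 0.43 for noFYC).
condition,lineup_type,outcome,count
FYC,culprit_present,suspect,71
FYC,culprit_present,filler,26
FYC,culprit_present,rejection,61
FYC,culprit_absent,suspect,7
FYC,culprit_absent,filler,38
FYC,culprit_absent,rejection,102
noFYC,culprit_present,suspect,69
noFYC,culprit_present,filler,23
noFYC,culprit_present,rejection,30
noFYC,culprit_absent,suspect,5
noFYC,culprit_absent,filler,48
noFYC,culprit_absent,rejection,79
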