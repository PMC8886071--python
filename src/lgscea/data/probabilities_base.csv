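# One-year outcome and complication probabilities, all seizure types.
# Seizure-freedom and >50%-reduction rows are discrete (mutually exclusive)
# outcomes: the freedom rate has already been subtracted from the inclusive
# >50%-reduction rate, so p_red is "reduced >50% but not seizure-free".
name,kind,arm,base,low,high
p_red_vns,probability,vns,0.441,0.323,0.560
p_free_vns,probability,vns,0.052,0.023,0.092
p_red_cc,probability,cc,0.470,0.380,0.560
p_free_cc,probability,cc,0.160,0.100,0.230
p_infection,probability,vns,0.024,0.015,0.024
p_other_vns,probability,vns,0.014,0.014,0.028
p_deficit,probability,cc,0.006,0.006,0.050
p_reop,probability,cc,0.066,0.066,0.100
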