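# Atonic-seizure scenario: overlays only the four seizure-outcome
# probabilities; complication probabilities and all costs are shared with
# the base case.
name,kind,arm,base,low,high
p_red_vns,probability,vns,0.313,0.093,0.496
p_free_vns,probability,vns,0.228,0.066,0.449
p_red_cc,probability,cc,0.320,0.190,0.420
p_free_cc,probability,cc,0.480,0.310,0.650
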