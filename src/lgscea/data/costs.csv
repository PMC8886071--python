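# One-year procedure and complication costs (USD, undiscounted).
# c_infection and c_reop default to the respective index-procedure cost.
# c_other_vns and c_deficit have no published estimate; the bundled bases
# (2200 and 11000) are the round-dollar solution recovered by the
# calibration module from the reported expected strategy costs (30844 and
# 98991): the exact solves are 2201.14 and 11033.33, and dollar rounding of
# the targets admits +/-35.7 and +/-83.3 around them. Their ranges are wide
# sensitivity scans, not uncertainty intervals around an estimate.
name,kind,arm,base,low,high
c_vns_index,cost,vns,30091,20000,40000
c_cc_index,cost,cc,92800,72900,178800
c_infection,cost,vns,30091,0,100000
c_other_vns,cost,vns,2200,0,100000
c_deficit,cost,cc,11000,0,500000
c_reop,cost,cc,92800,0,500000
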