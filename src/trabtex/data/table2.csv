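# Observer-score x fracture cross-tabulation of the 304-subject cohort.
# The six cells are the unique completion of the published margins:
#   fractured row total 115; fracture-free row printed as 48/111/30;
#   column totals dense 49, alternating 146, sparse 109; grand total 304.
# Hence fractured dense = 49-48 = 1, alternating = 146-111 = 35,
# sparse = 109-30 = 79 (sum 115, consistent).
fracture,score,count
1,dense,1
1,alternating,35
1,sparse,79
0,dense,48
0,alternating,111
0,sparse,30
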