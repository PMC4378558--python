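# Default linear-score feature weights, one line per peak-pair group.
# Columns: group  mz_distance  intensity_distance  supporting  neutral_loss  missing
# Trained by logistic regression on annotated CID envelope matches; the
# missing-peak feature is unused for the 2-peak group ("-").
2   3.237  0.851  -1.517  -2.491  -
3   4.987  1.565  -1.471  -0.810  0.277
4   3.942  1.448  -1.958  -0.795  0.386
5+  3.820  1.349  -0.992  -0.343  0.096
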