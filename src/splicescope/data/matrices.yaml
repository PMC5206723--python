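# Shapiro-Senapathy-style per-position nucleotide percentage weights for
# human splice sites.  Positions are relative to the exon/intron boundary:
# negative = exonic for the donor / intronic for the acceptor.  Values are
# editable; the scaled score is invariant to affine rescaling per matrix.
donor:
  site_type: donor
  positions: [-3, -2, -1, 1, 2, 3, 4, 5, 6]
  weights:
    -3: {A: 33.0, C: 37.0, G: 18.0, T: 12.0}
    -2: {A: 60.0, C: 13.0, G: 12.0, T: 15.0}
    -1: {A: 8.0, C: 4.0, G: 81.0, T: 7.0}
    1: {A: 0.0, C: 0.0, G: 100.0, T: 0.0}
    2: {A: 0.0, C: 0.0, G: 0.0, T: 100.0}
    3: {A: 59.0, C: 3.0, G: 35.0, T: 3.0}
    4: {A: 71.0, C: 8.0, G: 12.0, T: 9.0}
    5: {A: 6.0, C: 6.0, G: 84.0, T: 4.0}
    6: {A: 16.0, C: 16.0, G: 22.0, T: 46.0}
acceptor:
  site_type: acceptor
  positions: [-13, -12, -11, -10, -9, -8, -7, -6, -5, -4, -3, -2, -1, 1]
  weights:
    -13: {A: 10.0, C: 31.0, G: 12.0, T: 47.0}
    -12: {A: 10.0, C: 32.0, G: 11.0, T: 47.0}
    -11: {A: 9.0, C: 33.0, G: 11.0, T: 47.0}
    -10: {A: 9.0, C: 34.0, G: 10.0, T: 47.0}
    -9: {A: 9.0, C: 36.0, G: 9.0, T: 46.0}
    -8: {A: 9.0, C: 38.0, G: 9.0, T: 44.0}
    -7: {A: 9.0, C: 40.0, G: 8.0, T: 43.0}
    -6: {A: 8.0, C: 42.0, G: 7.0, T: 43.0}
    -5: {A: 8.0, C: 43.0, G: 6.0, T: 43.0}
    -4: {A: 24.0, C: 31.0, G: 21.0, T: 24.0}
    -3: {A: 3.0, C: 74.0, G: 1.0, T: 22.0}
    -2: {A: 100.0, C: 0.0, G: 0.0, T: 0.0}
    -1: {A: 0.0, C: 0.0, G: 100.0, T: 0.0}
    1: {A: 28.0, C: 14.0, G: 49.0, T: 9.0}
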