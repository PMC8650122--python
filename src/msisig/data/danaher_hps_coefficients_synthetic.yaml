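# SYNTHETIC stand-in weights for the Danaher hypermutation predictor score.
#
# The published coefficient table from the original Danaher et al. article
# is not bundled here; these unit-magnitude weights keep the score
# computable and correctly oriented (higher in hypermutated tumors).
# Signs follow gene behavior in MSI-high tumors: the four genes that other
# MSI signatures treat as down-regulated carry -1, the rest +1.
# Replace with the published table for faithful absolute HPS values; the
# final HPS is cohort Z-scored, so only relative weights matter.
coefficients:
  EPM2AIP1: -1.0
  TTC30A: -1.0
  SMAP1: -1.0
  RNLS: -1.0
  WNT11: 1.0
  SFXN1: 1.0
  SREBF1: 1.0
  TYMS: 1.0
  EIF5AL1: 1.0
  WDR76: 1.0
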