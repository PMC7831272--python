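"""ChIP-qPCR and RT-qPCR arithmetic.

Percent input adjusts the input Ct for its dilution, fold enrichment
compares a positive against a negative locus (2^ddCt, oriented so
enrichment > 1), and relative expression is the classic 2^-ddCt
normalized to a housekeeping gene.
"""

from acetylink.qpcr import fold_enrichment, percent_input, relative_expression

# ChIP well at Ct 25 vs a 1/16 input aliquot at Ct 20:
pct = percent_input(ct_chip=25.0, ct_input=20.0, input_fraction=1 / 16)
print(f"percent input          : {pct:.3f}%   (adjusted input Ct 16, dCt 9)")

# positive locus dCt 5 vs negative locus dCt 8 -> 2^3 = 8-fold enriched
fold = fold_enrichment(dct_positive=5.0, dct_negative=8.0)
print(f"ChIP fold enrichment   : {fold:.1f}x   (ddCt = 3)")

# target gene Ct 24 (reference 18) vs calibrator 26 (reference 18):
rel = relative_expression(24.0, 18.0, 26.0, 18.0)
print(f"relative expression    : {rel:.1f}x   (ddCt = -2, 2^-ddCt)")
# One qPCR cycle is a factor of two throughout: dCt differences convert
# directly to fold changes.
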