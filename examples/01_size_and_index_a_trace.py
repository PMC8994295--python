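"""Size a fragment-analysis trace and compute its expansion index.

Builds a small GeneMapper-style peak ladder for a repeat allele of 41 units
with somatic expansion peaks to the right and a stutter shoulder to the
left, calibrates bp -> repeat units against the 37/44/50 sizing standards,
calls the modal allele, and computes the 5%-threshold expansion index.
"""
from repeatmosaic import traceio, instability

calib = traceio.fit_calibration(traceio.default_sizing_standards())
print(f"calibration: {calib.slope_bp_per_repeat:.2f} bp/repeat, "
      f"flank {calib.intercept_bp:.1f} bp")

# peak table: (fragment size bp, height RFU); 384 bp = 41 repeats
peaks = [(378.0, 18.0), (384.0, 100.0), (390.0, 60.0), (396.0, 40.0), (402.0, 4.0)]
table = traceio.PeakTable("patient-1:cerebellum", "XDP", tuple(peaks))
dist = traceio.call_distribution(table, calib)
print(f"modal allele: {dist.modal_repeat} repeats")

res = instability.expansion_index(dist, threshold_fraction=0.05)
print(f"expansion index:   {res.expansion_index:.4f}")
print(f"contraction index: {res.contraction_index:.4f}")
print(f"peaks retained:    {res.peaks_retained}")

# The expansion index is the normalized-height-weighted mean repeat gain over
# peaks longer than the modal allele; the 402 bp peak (4 RFU < 5% of 100)
# is excluded by the relative threshold, so only +1 and +2 peaks contribute:
# (60*1 + 40*2) / (18 + 100 + 60 + 40) = 0.6422.
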