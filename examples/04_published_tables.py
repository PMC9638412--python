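"""Confusion-matrix and diagnostic-time arithmetic on published counts.

Reproduces the reported sensitivity/specificity/accuracy figures from the raw
TP/FP/FN/TN counts, and the diagnostic-time reductions from the per-slide
timing table.  Note the two display conventions: some reports round half-up,
others truncate; both are supported.
"""

from pnikit.evaluation import (
    ConfusionMatrix,
    TimingRecord,
    mean_accuracy,
    metrics,
    time_reduction,
)

nerve_id = metrics(ConfusionMatrix(tp=106, fp=3, fn=8, tn=15), convention="half_up")
print(f"nerve identification (n=132):  sens {nerve_id.sensitivity}%  "
      f"spec {nerve_id.specificity}%  acc {nerve_id.accuracy}%")

roi = metrics(ConfusionMatrix(tp=116, fp=14, fn=7, tn=54), convention="half_up")
print(f"PNI detection, ROI level (n=191):  sens {roi.sensitivity}%  "
      f"spec {roi.specificity}%  acc {roi.accuracy}%")

first = metrics(ConfusionMatrix(tp=12, fp=7, fn=4, tn=384))   # truncating convention
second = metrics(ConfusionMatrix(tp=11, fp=8, fn=1, tn=385))
print(f"WSI validation:  reader 1 acc {first.accuracy}%, reader 2 acc {second.accuracy}%, "
      f"mean {mean_accuracy([first, second])}%")

timings = [TimingRecord("S2018-xxx810", 54, 19), TimingRecord("S2012-xxx201", 37, 126)]
analysis = time_reduction(timings)
for slide, pct in analysis.per_slide_pct.items():
    print(f"  {slide}: {pct:+.1f}% diagnostic-time change")
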