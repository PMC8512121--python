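"""Recompute classifier quality metrics from raw confusion counts.

The bundled table holds one-vs-rest confusion counts of an evolved MRI
brain-tumor classifier (normal / glioma grades for dataset 1, glioma /
meningioma / pituitary for dataset 2).  The nine derived metrics are printed
at three decimals; TPR is sensitivity, TNR specificity, PPV precision, and
F1 their harmonic-mean summary with recall.
"""

import pandas as pd

from hawkopt import load_confusion_table, metrics_table

counts = load_confusion_table("ehho")
metrics = metrics_table(counts).round(3)
report = pd.concat(
    [counts[["dataset", "class", "TP", "FP", "TN", "FN"]], metrics], axis=1
)
print(report.to_string(index=False))
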