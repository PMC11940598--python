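"""The five evaluation metrics computed from an explicit confusion table.

Reproduces a hand-checkable binary example: TP=50, TN=40, FP=5, FN=5.
"""

from eegfuse.metrics import ConfusionTable, compute_metrics

table = ConfusionTable.from_binary_counts(tp=50, tn=40, fp=5, fn=5)
report = compute_metrics(table)

print("confusion matrix (rows=truth, cols=prediction):")
print(table.matrix)
print(f"accuracy  {report.accuracy:.4f}   (correct/total = 90/100)")
pos = report.per_class[1]
print(f"positive-class precision/recall/F1: "
      f"{pos['precision']:.4f} / {pos['recall']:.4f} / {pos['f1']:.4f}  (all 50/55)")
print(f"MCC       {report.mcc:.5f}   (1975/2475)")
print("as a percent row:", report.csv_row())
# MCC stays informative under imbalance: it is the correlation between
# the truth and prediction indicators, 1.0 only for perfect agreement.
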