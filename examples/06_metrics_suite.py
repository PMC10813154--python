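"""The nine-metric evaluation suite on a worked confusion matrix.

For TP=3, TN=4, FP=1, FN=2 every metric can be computed by hand, which
makes this the reference example for the metric definitions, including
the two specificity conventions used in Gmean.
"""

from ecgdyn import ConfusionCounts, auc_score, binary_metrics

c = ConfusionCounts(TP=3, TN=4, FP=1, FN=2)
rep = binary_metrics(c)
print("confusion counts: TP=3, TN=4, FP=1, FN=2")
print(f"  Accuracy  {rep.accuracy:6.2f}%   (TP+TN)/total")
print(f"  Precision {rep.precision:6.2f}%   TP/(TP+FP)")
print(f"  Recall    {rep.recall:6.2f}%   TP/(TP+FN)")
print(f"  F1        {rep.f1:6.2f}%   harmonic mean")
print(f"  Kappa     {rep.kappa:7.4f}   chance-corrected agreement")
print(f"  MCC       {rep.mcc:7.4f}   full-range [-1, 1]")
print(f"  CSI       {rep.csi:7.4f}   TP/(TP+FP+FN)")
print(f"  Gmean     {rep.gmean:7.4f}   sqrt(Recall x TN/(TN+FP))")

alt = binary_metrics(c, specificity_mode="as_printed")
print(f"  Gmean (specificity as TN/(FN+TN)): {alt.gmean:7.4f}")

auc = auc_score([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1])
print(f"\nrank AUC of labels [1,0,1,0] with scores [0.9,0.8,0.3,0.1]: "
      f"{auc} (3 of 4 positive-negative pairs concordant)")
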