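"""Classify a synthetic cohort with the direct and stepwise schemes.

Direct: one three-class QDA on two recovery-stage features.  Stepwise:
QDA separating HC from migraineurs first, then a second QDA separating
CM from MOH among predicted migraineurs; the composed 3x3 confusion
matrix uses leave-one-out predictions with predicted-label routing.
"""

from nirsmat import extract_feature_table, simulate_cohort
from nirsmat.classify import direct_classify, stepwise_classify

table = extract_feature_table(simulate_cohort(seed=0))

direct = direct_classify(table, seed=0)
print("== direct (3-class QDA) ==")
print(
    f"train {direct.train_accuracy:.1%}  test {direct.test_accuracy:.1%}  "
    f"LOOCV {direct.loocv_accuracy:.1%}"
)

stepwise = stepwise_classify(table, seed=0, cm_moh_feature_set="set1")
print("\n== stepwise (HC vs migraine, then CM vs MOH) ==")
s1, s2 = stepwise.extras["stage1"], stepwise.extras["stage2"]
print(f"stage 1 (HC vs migraine): train {s1['train_accuracy']:.1%}  "
      f"LOOCV {s1['loocv_accuracy']:.1%}  test {s1['test_accuracy']:.1%}")
print(f"stage 2 (CM vs MOH):      train {s2['train_accuracy']:.1%}  "
      f"LOOCV {s2['loocv_accuracy']:.1%}  test {s2['test_accuracy']:.1%}")
print("\ncomposed three-class result:")
print(stepwise.to_text())
# Sensitivity = fraction of a group correctly identified; specificity =
# fraction of the others not mislabelled as that group.  The stepwise
# scheme recovers the planted group structure far better than the
# direct scheme, mirroring how separating HC first simplifies the
# CM/MOH decision.
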