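"""Metric conventions used in reporting.

MAE comparisons use plain relative change; AUC comparisons subtract the
0.5 chance baseline from both values first, so a move from 0.598 to 0.604
is a 6.1% gain in discrimination above chance, not a 1% gain in raw AUC.
Confidence intervals are 2.5th-97.5th percentile bootstrap intervals.
"""

import numpy as np

from metastack import (adjusted_auc_pct_change, auc, calibration_in_the_large,
                       mae, pct_change_mae, percentile_ci)

print("MAE change 4.63 -> 4.52:",
      f"{pct_change_mae(4.63, 4.52):+.2f}% (positive = error went down)")
print("AUC change 0.598 -> 0.604 above chance:",
      f"{adjusted_auc_pct_change(0.598, 0.604):+.2f}%")

rng = np.random.default_rng(0)
q = np.clip(0.375 + rng.normal(0, 0.08, 5000), 0.02, 0.98)  # true risks
y = (rng.random(5000) < q).astype(float)
p = np.clip(q + rng.normal(0, 0.12, 5000), 0, 1)  # noisy risk score
print("AUC of a weak risk score:", f"{auc(y, p).value:.3f}")
mean_pred, rate, diff = calibration_in_the_large(y, p)
print(f"calibration-in-the-large: mean predicted {mean_pred:.3f} "
      f"vs event rate {rate:.3f} (difference {diff:+.4f})")

replicates = rng.normal(4.6, 0.05, 200)
lo, hi = percentile_ci(replicates)
print(f"bootstrap MAE replicates: point {replicates.mean():.3f}, "
      f"95% percentile CI [{lo:.3f}, {hi:.3f}]")
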