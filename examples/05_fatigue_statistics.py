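"""Paired comparison of visual-fatigue questionnaire scores.

Ten symptoms rated 1-5 after mixed-reality (MR) and virtual-reality
(VR) sessions are compared with the Wilcoxon signed-rank test under a
Bonferroni-corrected significance level of 0.05 / 10 = 0.005.  Negative
Z means the VR score tends to be higher.
"""

import numpy as np

from ssvep_depth_lab import bonferroni_alpha, wilcoxon_signed_rank

rng = np.random.default_rng(0)
alpha = bonferroni_alpha(0.05, 10)
print(f"per-symptom significance level: {alpha}\n")

symptoms = {
    # VR systematically one step worse for double vision
    "double vision": ([2, 2, 2, 2, 2, 1, 1, 1, 1, 3],
                      [2, 2, 2, 2, 2, 2, 2, 2, 2, 5]),
    # no systematic difference
    "headache": ([1, 1, 2, 1, 1, 1, 2, 1, 1, 1],
                 [1, 1, 1, 1, 2, 1, 2, 1, 1, 1]),
}
for name, (mr, vr) in symptoms.items():
    res = wilcoxon_signed_rank(mr, vr, label=name, significance_level=alpha)
    verdict = "significant" if res.significant else "not significant"
    print(f"{name:>13}: MR median {res.median_a:.1f} "
          f"(IQR {res.iqr_a[0]:.1f}-{res.iqr_a[1]:.1f}), "
          f"VR median {res.median_b:.1f} "
          f"(IQR {res.iqr_b[0]:.1f}-{res.iqr_b[1]:.1f}), "
          f"Z = {res.z:.3f}, p = {res.p:.3f} -> {verdict} at {alpha}")
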