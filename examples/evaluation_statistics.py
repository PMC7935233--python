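"""The evaluation statistics on their own: AUC, d', Friedman chi-square, W.

Small worked inputs, each printed with what the number means.
"""

import numpy as np

import ppskit as pk

# --- AUC and the binormal effect-size scale ---------------------------------
# AUC = P(random responder outscores random non-responder).  Under the
# equal-variance binormal model a 'large' effect d' = 0.8 corresponds to:
print(f"AUC at d'=0.8: {pk.auc_from_dprime(0.8):.3f}   (the clinical 'large effect' bound)")

scores = np.array([3, 1, 2, 5, 4, 6, 2, 7], dtype=float)
labels = np.array([1, 1, 1, 2, 1, 2, 2, 2])  # 1 = non-responder, 2 = responder
roc = pk.roc_auc_ci(scores, labels)
print(f"toy cohort AUC: {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")

cut = pk.choose_cutpoint(scores, labels)
stats = pk.classification_stats(scores >= cut, labels)
print(f"Youden cutpoint {cut}: sensitivity {stats.sensitivity:.2f}, "
      f"specificity {stats.specificity:.2f}, accuracy {stats.accuracy:.2f}")

# --- group-level concordance -------------------------------------------------
# 57 subjects whose event count increased from run-in to treatment, without
# exception: chi-square equals N and Kendall's W = 1 (complete concordance).
pri = np.random.default_rng(0).integers(0, 8, size=57).astype(float)
active = pri + 1
res = pk.friedman_two_conditions(pri, active)
print(f"\nall-increase group: chi2(N={res.n}, df={res.df}) = {res.chi2:.0f}, "
      f"p = {res.p:.2g}, W = {res.w:.2f}")

# a chi-square of 36 over 72 pairs corresponds to moderate concordance:
print(f"W from chi2=36, N=72: {pk.kendalls_w_from_friedman(36, 72, 2):.2f}")
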