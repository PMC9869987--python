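"""Sample-size planning by interval accuracy rather than power.

Plans the three study sizes of a lean determinant project: a validity
study needing a tight interval around a high correlation, a main study
tolerating a wider interval around a possibly small correlation, and
an expert panel sized to pin down a standard deviation.
"""

from ciberlite import aipe_n_correlation, aipe_n_sd, bonferroni_alpha, enumerate_design_terms

# Convergent-validity study: expect r ~ .80 between short and full
# composites, want a 95% CI of half-width .05.
plan = aipe_n_correlation(rho=0.80, halfwidth=0.05, level=0.95)
print(f"validity study: n = {plan.n}  (CI half-width {plan.halfwidth_at_n:.4f})")

# Main study: even for a weak correlation (r = .10), a half-width of .10.
plan = aipe_n_correlation(rho=0.10, halfwidth=0.10, level=0.95)
print(f"main study:     n = {plan.n}")

# Expert panel: estimate an SD of about 0.7 with half-width 0.3.
plan = aipe_n_sd(sigma=0.7, halfwidth=0.3, level=0.95)
print(f"expert panel:   n = {plan.n}  (SD intervals widen as the estimate grows)")

# Design bookkeeping for a 2x2x2 within-subjects study with three outcomes.
terms, total = enumerate_design_terms(3, 3, ["Att", "PN", "PBC"])
print(f"factorial terms per outcome: {len(terms)}; across outcomes: {total}")
print(f"alpha .005 split over 3 outcomes: {bonferroni_alpha(0.005, 3):.7f}")
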