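"""Convergent validity: compare construct correlations across two samples.

Two independent samples answer the same instrument; Cohen's Q checks,
pair by pair, whether the correlation structure among intention and
the three determinants differs between them. Intervals are at the 99%
level, the stricter level used for key estimates when many intervals
are reported at once.
"""

from ciberlite import (
    BehaviorCondition,
    SyntheticResponseSpec,
    build_q_panel,
    compare_correlation_matrices,
    raa_instrument,
    raa_latent_corr,
    render,
    simulate_responses,
)

instrument = raa_instrument("not smoking at all in the next month")
corr = raa_latent_corr(instrument, det_target_r=0.4)
means = {i: 3.0 for i in instrument.item_ids}
cond = BehaviorCondition("smoking", means, corr)

sample_a = simulate_responses(SyntheticResponseSpec(205, instrument, (cond,), seed=1))
sample_b = simulate_responses(SyntheticResponseSpec(205, instrument, (cond,), seed=2))

comparisons = compare_correlation_matrices(sample_a, sample_b, instrument, level=0.99)
for c in comparisons:
    verdict = "consistent" if c.includes_zero else "DIFFERS"
    print(
        f"{c.labels[0]:15s} x {c.labels[1]:15s} r1={c.r1:+.2f} r2={c.r2:+.2f} "
        f"Q={c.q:+.3f} [{c.ci.lower:+.3f}; {c.ci.upper:+.3f}]  {verdict}"
    )

render(build_q_panel(comparisons), "scratch_q_panel_example.svg")
print("Both samples come from one population, so all Q intervals should include 0.")
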