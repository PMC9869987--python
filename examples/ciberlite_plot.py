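"""Build and render the determinant-selection plot for one behavior.

Simulates Likert responses where attitude correlates most with
intention but has low means (much room for improvement), summarizes
the determinants, and writes the grayscale bars-plus-diamonds figure.
"""

from ciberlite import (
    BehaviorCondition,
    SyntheticResponseSpec,
    build_ciberlite_model,
    raa_instrument,
    raa_latent_corr,
    render,
    room_for_improvement,
    simulate_responses,
    summarize_determinants,
)

instrument = raa_instrument("not drinking any coffee at all in the next month")
means = {
    "att_instrumental": 2.6, "att_experiential": 2.1,
    "pn_injunctive": 2.4, "pn_descriptive": 2.9,
    "pbc_capacity": 4.0, "pbc_autonomy": 4.3,
    "intention": 2.2,
}
corr = raa_latent_corr(
    instrument, det_target_r={"attitude": 0.55, "perceived_norm": 0.35, "pbc": 0.20}
)
spec = SyntheticResponseSpec(
    n_respondents=415,
    instrument=instrument,
    behaviors=(BehaviorCondition("coffee", means, corr),),
    seed=23,
)
dataset = simulate_responses(spec)
summary = summarize_determinants(dataset, instrument, level=0.95)

for block in summary.blocks:
    ci = block.correlation.ci
    print(
        f"{block.label:15s} mean {block.generic_mean:.2f} "
        f"(room for improvement {room_for_improvement(block.generic_mean, instrument.scale):.2f})  "
        f"r with intention {block.correlation.r:.2f} [{ci.lower:.2f}; {ci.upper:.2f}]"
    )

path = render(build_ciberlite_model(summary), "scratch_ciberlite_example.svg")
print(f"figure written to {path}")
print("High room-for-improvement + high correlation marks the determinant to target.")
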