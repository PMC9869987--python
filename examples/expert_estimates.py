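"""Aggregate an expert panel's determinant estimates and gauge their spread.

Simulates 45 experts rating 8 behaviors x 3 determinants on a 1-5
scale with unit spread, then reports per-parameter means (t intervals)
and SDs (chi-square intervals). SD interval lower bounds above 0.5
indicate the experts genuinely disagree.
"""

from ciberlite import (
    SyntheticExpertSpec,
    aggregate_expert_estimates,
    simulate_expert_estimates,
)

behaviors = [f"behavior_{i + 1}" for i in range(8)]
determinants = ["attitude", "perceived_norm", "pbc"]
cells = tuple((b, d) for b in behaviors for d in determinants)

spec = SyntheticExpertSpec(
    n_experts=45,
    cells=cells,
    true_means=tuple([3.0] * len(cells)),
    sds=tuple([1.0] * len(cells)),
    seed=3,
)
panel = simulate_expert_estimates(spec)
agg = aggregate_expert_estimates(panel, level=0.95)

print(agg.table.head(6).round(2).to_string(index=False))
print(f"... ({agg.n_cells} parameters in total)")
print(f"mean of per-parameter SDs: {agg.mean_of_sds:.2f}")
lo = agg.table["sd_lower"]
print(f"SD CI lower bounds range {lo.min():.2f}-{lo.max():.2f}; "
      f"{int((lo > 0.5).sum())}/{agg.n_cells} exceed 0.5 (non-trivial disagreement)")
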