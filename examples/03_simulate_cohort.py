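"""Generate a calibrated synthetic cohort and recover its parameters.

The generator draws cluster sizes from the observed mix (76% doublets, 16%
triplets, 8% four-plus), simulates each transit through an equal 7-um
bifurcation with per-size junction calibration, and the estimation pipeline
then recovers the per-size dissociation frequencies and the per-junction
break probability from the event table alone.
"""

from ctctransit import (
    default_config,
    dissociation_frequency,
    fit_junction_probability,
    generate_cohort,
)

cfg = default_config(n_clusters=20_000, seed=11)
clusters, events, viability = generate_cohort(cfg)

freq = dissociation_frequency(events, "size_class")
print("Dissociation frequency by size class (target 51 / 67 / 91%):")
for _, row in freq.iterrows():
    print(
        f"  {row['size_class']:>3s}-cell: {100 * row['frequency']:5.1f}% "
        f"(95% CI {100 * row['ci_low']:.1f}-{100 * row['ci_high']:.1f}, n={int(row['n'])})"
    )

p_hat, se = fit_junction_probability(events)
print(f"\nMLE per-junction break probability: {p_hat:.3f} (SE {se:.3f})")
print("A value near 0.5 reproduces the doublet rate; the heavier break rates")
print("of larger clusters follow from their extra junctions, not stickier cells.")
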