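# Methods

## The physical setting

Capillary beds impose two mechanical regimes on a circulating tumor cell
(CTC) cluster: constriction (vessels of 5–10 µm force clusters into a
single-file chain) and bifurcation (each junction point splits flow between
two daughter vessels of possibly different calibre). The package models a
cluster's passage through one engineered bifurcation — or a cascade of
them — as three coupled stochastic steps: junction breakage, fragment
routing, and per-cell lysis.

## Device geometry

Devices are rectangular PDMS microchannels characterized by width `a`,
height `b` and length `L`. Because the cross-sections are rectangular, all
branching design is done on the *effective* (equivalent circular) diameter

    de = 1.3 (a·b)^0.625 / (a + b)^0.25,

an empirical correction for channels below ~10 µm. Parent channels obey
Murray's minimal-work law on effective diameters, `d0³ = d1³ + d2³`; the
catalog constructor solves the effective-diameter relation numerically for
the parent width at fixed 7 µm height so every catalog entry satisfies the
law to 10⁻⁶ by construction. Constricted devices (bifurcating and linear)
have 7 µm channel height; the nonconstricted control is 20 µm.

Laminar resistance of a rectangular duct uses the one-term truncation of
the exact series solution, with `h = min(a, b)`, `w = max(a, b)`:

    R = 12 µ L / (w h³ (1 − (192/π⁵)(h/w) tanh(π w / 2h))).

The tanh factor matters: the common shortcut `1 − 0.63 h/w` is ~13% wrong
for square ducts, while the truncation above stays within ~0.7% of a
20-term series across aspect ratios 1–3 (the test suite checks this against
an independently coded series oracle). Flow split is purely resistive,
`f2 = R1/(R1+R2)`: branch angles and symmetry are stored on the device but
deliberately do not enter the split, reflecting the observation that at
capillary Reynolds numbers pathing is governed by hydrodynamic resistance,
not inertia.

Defaults: viscosity 1.0×10⁻³ Pa·s (PBS ≈ water at room temperature),
segment length 100 µm for all branches (splits depend only on resistance
ratios, so equal lengths make them a function of cross-sections alone),
driving pressure 30 cmH₂O = 2941.995 Pa (98.0665 Pa per cmH₂O). Daughter
widths for the wide-angle variants (EWA/EWS/UWA/UWS) are not part of the
printed nomenclature; they default to 7/7 and 5/9 and are flagged
`placeholder_dims` in the catalog.

## Junction fragmentation model

A cluster of `n` cells in single file has `n − 1` junctions; junction `i`
joins cells `i` and `i+1`. Each junction breaks with probability `p`,
independently of the others, so

    P(at least one dissociation) = 1 − (1 − p)^(n−1).

Broken junctions partition the chain into fragments (maximal unbroken
runs); fragment sizes always sum to `n`. The independence assumption can be
relaxed through a Gaussian-copula shared frailty: each junction's uniform
is generated from `Φ(√ρ·Z + √(1−ρ)·Zᵢ)` with a cluster-level `Z`, keeping
the marginal break probability exactly `p` while coupling failures
(`ρ = 0` default, `ρ = 1` all-or-none). This exists to probe the caveat
that junction failures within one cluster may not be independent.

## Routing

Fragments enter daughter branches in transit order. Two rules:

* `independent_flow_split` — each fragment goes to branch 2 with
  probability `f2`.
* `occlusion_alternating` (default) — the leading fragment follows the bare
  split; each later fragment sees the branch occupied by the fragment ahead
  with its resistance multiplied by an occlusion factor `κ ≥ 1`, so in an
  equal bifurcation consecutive fragments land in different branches with
  probability `κ/(κ+1)`.

When the bare split is strongly unequal (`f2 ≥ 0.9`) the larger branch
captures every fragment under both rules, matching the observation that in
strongly unequal bifurcations all components of dissociating clusters exit
via the larger daughter.

`κ` is a calibration, not a physical measurement. A cluster with `k` broken
junctions keeps all fragments in one branch of an equal bifurcation with
probability `(κ+1)^−k`; mixing over the break-count distribution implied by
the default size mix and per-size junction probabilities (conditioned on at
least one break) and setting the different-branch probability to the
observed 88% gives `κ = 6.2958` (`calibrate_kappa` recomputes this from the
closed form). Under this mixed-cohort calibration, dissociating doublets
alone split branches 86.3% of the time.

## Lysis

Per-cell death flags are drawn from per-condition probabilities keyed as
`{geometry}_{unit}_{arm}` (e.g. `bifurcation_cluster_untreated`). Defaults:
bifurcation singles 15% untreated / 32% cytochalasin-D; cells within
clusters 4.6% / 27.3%. Lysed cells are annotations by default
(`annotate` mode: reported fragment sizes keep them); `remove` mode deletes
them from fragments before reporting, preserving the accounting identity
`Σ fragment sizes + removed = n`. Non-bifurcation condition rates are not
printed anywhere and ship as flagged placeholders (roughly half the
bifurcation rates, qualitatively "lower"). Transit-time mechanics are out
of scope; times are optional pass-through fields.

## Synthetic cohorts and calibration

The generator emulates the statistical structure of live-imaging transit
data; it does not emulate images, shear-vesicle biogenesis, or cell–wall
mechanics. One cohort is defined by a validated `CohortConfig`:

| parameter | default | meaning |
|---|---|---|
| `size_pmf` | 2: 0.76, 3: 0.16, 4+: 0.08 | observed cohort size mix |
| `tail` | geometric q = 0.5 on 4..10 | within-4+ sizes; cap 10 echoes the largest collected cluster; the composition inside 4+ is a modelling convention, never measured |
| `per_size_dissociation` | 0.51 / 0.67 / 0.91 | target per-class dissociation frequencies |
| `per_geometry_dissociation` | equal 0.83, unequal 0.27, 7 µm 0.733, 9 µm 0.424, UNA_5.5/7 0.453, UNA_5/9 0.089 | arm-level all-cluster means |
| `cytod_dissociation` | UNA_5/9: all 0.667, doublets 0.577 | treatment replaces the arm target outright (arm-level means are what is known, so treatment is not modelled as a multiplier) |
| `routing.kappa` | 6.2958 | occlusion calibration (above) |
| `volume_model` | lognormal, σ_log 0.4; per-cell means 2.0 pL (7 µm) / 3.0 pL (9 µm); dissociating multipliers 1.41 / 1.80 | only the dissociating:intact mean ratios are measured; σ and the per-cell means are conventions chosen at realistic MDA-MB-231 scale |
| `seed` | 0 | master seed |

Calibration entries are *target frequencies*, the quantities actually
reported; per-junction probabilities are derived by inverting the model:
for a fixed size class `p = 1 − (1−F)^(1/(n−1))`, and for pooled classes
(the 4+ tail, or a whole-cohort geometry arm) by solving
`E_sizes[1 − (1−p)^(n−1)] = F` with Brent's method under the configured
size mix. Parameter recovery by the estimation module is therefore exact in
expectation — the design goal, since the package's tests are
parameter-recovery exercises.

The pooled equal-arm mean (83%) is kept as its own calibration arm,
separate from the per-device equal arms (73.3%, 42.4%): the source arms are
distinct replicate sets and are not mutually consistent as a single
hierarchy, so the generator reproduces each arm as reported rather than
reconciling them. Likewise the pre-collection composition cohort
(mean 5 ± 3.9 cells) differs from the live-imaging size mix and is treated
as a separate cohort, not reconciled.

Seeding: each cluster's draws come from a dedicated substream keyed on
`(seed, cluster_index)` (`numpy` `SeedSequence` spawn keys), so growing a
cohort never perturbs earlier clusters, and identical configs produce
byte-identical CSVs.

## Estimation

* Frequencies: dissociating / transiting clusters per group; single cells
  are excluded (no junctions); empty groups are missing, never zero. Wilson
  score intervals at 95% (statsmodels). Replicate-level mean ± SD
  aggregation is available by grouping per replicate and averaging.
* Junction MLE: the likelihood treats each cluster as a Bernoulli trial
  with success probability `1 − (1−p)^(nᵢ−1)`; the root of the analytic
  score is found by Brent's method on [10⁻¹², 1−10⁻¹²], with closed forms
  at the boundaries and for doublet-only data (sample proportion, exact).
  Standard errors come from a central-difference observed information with
  `p̂` clamped to [10⁻⁹, 1−10⁻⁹].
* The predicted table re-evaluates the closed form from `p̂`
  bit-for-bit — predictions are never cached separately from the estimate.
* The 4+ class prediction uses junction count 3 (quadruplets) in the
  ladder; cohort-level recovery of the pooled 4+ rate goes through the
  empirical tail mix instead.
* Fold changes are plain ratios of arm means with report-style rounding
  (one decimal or nearest integer). Significance machinery (t tests,
  ANOVA) is deliberately not reproduced.

## What passing tests do and do not show

The generator's calibration targets are the quantities the estimator
recovers, so green parameter-recovery tests demonstrate the internal
consistency of model + generator + estimator and the correctness of the
inversion — not that real clusters obey the independent-junction model.
Real data depart in ways the generator does not emulate: adhesion
heterogeneity between cell lines and patients, volume-dependent breakage
(the association is reported but no functional form; an optional logistic
link is a natural extension and is left off by default), possible junction
correlation (`ρ > 0` is available but uncalibrated), deformable walls and
cell–wall friction, and endothelial or immune interactions.

## Problem sizes and numerics

Default verification runs use cohorts of 10,000–20,000 clusters (50,000
for size-mix checks), chosen so Monte Carlo standard errors are a few
tenths of a percentage point and three-standard-error bands are decisive.
Brent root-finding uses `xtol = 10⁻¹²`; Murray-law catalog consistency is
enforced to 10⁻⁶ µm³; duct-resistance truncation error is bounded at 1%
against a 20-term series. Degenerate inputs are defined explicitly: a
single-branch "bifurcation" (`d2 = 0`) returns the surviving diameter;
`n_junctions = 0` gives dissociation probability 0; `σ_log = 0` makes
volume draws exact means; all-intact or all-broken data put the MLE on the
boundary (0 or 1) before clamping for the standard error.
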