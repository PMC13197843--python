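# ctctransit

Simulation and analysis of **circulating tumor cell (CTC) cluster transit
through capillary bifurcations**.

CTC clusters are far more metastatic than equal numbers of single tumor
cells, yet to reach a distant organ they must squeeze through capillary beds
whose vessels repeatedly narrow and bifurcate. At capillary scale a cluster
unfolds into a single file of cells, and at each bifurcation the mechanical
load can break the cell–cell junctions that hold it together, scattering
smaller clusters and single cells into the daughter branches. `ctctransit`
packages the quantitative machinery for studying this process:

* **Device geometry** — a catalog of microfluidic capillary-bifurcation
  variants designed by Murray's law on effective diameters,
  `d0³ = d1³ + d2³` with `de = 1.3·(a·b)^0.625 / (a+b)^0.25` for a
  rectangular channel of width `a` and height `b`; rectangular-duct laminar
  resistances and the resulting daughter-branch flow splits
  `f2 = R1/(R1+R2)`.
* **Transit simulation** — a Bernoulli junction-fragmentation model: a
  cluster of `n` cells carries `n−1` junctions, each breaking with
  probability `p` (independently by default, with an optional shared-frailty
  correlation), so `P(≥1 dissociation) = 1 − (1−p)^(n−1)`; fragments are
  routed into branches by the flow split with an occlusion-aware rule, and
  per-cell lysis is drawn from per-condition death rates. Multi-level
  cascades chain bifurcations.
* **Estimation** — dissociation frequencies with Wilson intervals,
  maximum-likelihood estimation of the per-junction probability from mixed
  cluster sizes, predicted-vs-observed dissociation ladders, pathing
  preference, cohort composition (cluster:single ratio) and per-cell
  viability summaries, plus report rendering.
* **Synthetic cohorts** — a calibrated generator whose defaults reproduce
  the observed study conditions (size mix 76/16/8% for doublets/triplets/4+;
  per-size dissociation 51/67/91%; per-geometry arm means; cytochalasin-D
  treatment arms; lognormal cluster volumes with dissociating > intact), so
  the whole pipeline is testable end-to-end as a parameter-recovery
  exercise without any external data.

## Worked example

```python
from ctctransit import (
    default_config, generate_cohort, dissociation_frequency, fit_junction_probability,
)

cfg = default_config(n_clusters=20_000, seed=11)
clusters, events, viability = generate_cohort(cfg)
print(dissociation_frequency(events, "size_class"))
print(fit_junction_probability(events))
```

Running `python examples/03_simulate_cohort.py` (which does the above)
prints:

```
Dissociation frequency by size class (target 51 / 67 / 91%):
    2-cell:  50.8% (95% CI 50.0-51.6, n=15115)
    3-cell:  67.1% (95% CI 65.4-68.7, n=3245)
   4+-cell:  90.3% (95% CI 88.8-91.6, n=1640)

MLE per-junction break probability: 0.488 (SE 0.003)
```

The per-size frequencies recover the generator's calibration within Monte
Carlo error, and the fitted per-junction probability is close to the doublet
rate — the signature of the independent-junction model, in which larger
clusters break more often simply because they carry more junctions.

The other scripts in `examples/` cover the device catalog and flow splits,
the closed-form vs Monte Carlo junction model, geometry/treatment arms with
fold changes, and occlusion-aware routing plus bifurcation cascades. A thin
CLI mirrors the stages:

```bash
ctctransit design --catalog --out catalog.json
ctctransit simulate --device UNA_5/9 --n 10000 --seed 42 --out events.csv
ctctransit estimate --events events.csv --out report.json
ctctransit recover-calibration --seed 3
```

## Layout

```
src/ctctransit/    geometry, transit, estimation, synthetic, pipeline, cli
src/ctctransit/data/default_calibration.json   shipped calibration table
examples/          one narrative script per capability
tests/             unit, property and parameter-recovery suites
docs/methods.md    model description, calibration and design notes
```
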