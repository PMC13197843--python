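"""Synthetic cohorts with the statistical structure of observed transits.

The generator stands in for live-imaging event data: it samples cluster
sizes from the observed cohort mix (76% doublets, 16% triplets, 8% four-plus,
with a truncated-geometric tail inside the 4+ class), converts calibrated
arm-level dissociation *frequencies* into per-junction break probabilities by
inverting the independent-junction model under that size mix, simulates
transits through a chosen device, attaches lognormal cluster volumes whose
means differ between dissociating and intact clusters, and draws per-cell
death flags from per-condition rates. Because the calibration is expressed
as target frequencies, the estimation pipeline recovers the shipped numbers
up to Monte Carlo error by construction — which is exactly what makes the
generator a parameter-recovery test harness.

Seeding uses one master seed with per-cluster substreams derived from
``(seed, cluster_index)``, so changing the cohort size never changes the
draws of earlier clusters.
"""

from __future__ import annotations

import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq

from . import transit
from .geometry import BifurcationDevice, get_device
from .transit import (
    ClusterState,
    LysisMode,
    RoutingMode,
    TransitEvent,
    events_to_frame,
    lysis_condition,
    simulate_cohort,
)

__all__ = [
    "CohortConfig",
    "TailConfig",
    "VolumeConfig",
    "RoutingConfig",
    "load_default_calibration",
    "default_config",
    "sample_cluster_sizes",
    "sample_volumes",
    "expected_size_distribution",
    "invert_class_rate",
    "make_junction_lookup",
    "make_lysis_lookup",
    "generate_cohort",
]


def load_default_calibration() -> dict:
    """The shipped calibration table (arm frequencies, size mix, rates)."""
    with resources.files("ctctransit.data").joinpath("default_calibration.json").open() as fh:
        return json.load(fh)


class TailConfig(BaseModel):
    """Truncated-geometric size distribution inside the 4+ class:
    P(s) proportional to (1-q)**(s - min_size) for s in [min_size, max_size]."""

    q: float = 0.5
    min_size: int = 4
    max_size: int = 10

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("tail.q must be in (0, 1)")
        if not 2 <= self.min_size <= self.max_size:
            raise ValueError("tail sizes must satisfy 2 <= min_size <= max_size")
        return self

    def weights(self) -> dict[int, float]:
        sizes = range(self.min_size, self.max_size + 1)
        raw = {s: (1.0 - self.q) ** (s - self.min_size) for s in sizes}
        total = sum(raw.values())
        return {s: w / total for s, w in raw.items()}


class VolumeConfig(BaseModel):
    """Lognormal total-cluster-volume model, parameterized by the per-cell
    mean volume (pL) per capillary width and the dissociating:intact mean
    ratio per capillary width."""

    sigma_log: float = 0.4
    cell_mean_pl: dict[str, float] = Field(default_factory=lambda: {"7": 2.0, "9": 3.0})
    dissociating_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"7": 1.41, "9": 1.8}
    )

    @field_validator("sigma_log")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("sigma_log must be >= 0")
        return v


class RoutingConfig(BaseModel):
    mode: RoutingMode = RoutingMode.occlusion_alternating
    kappa: float = transit.DEFAULT_KAPPA

    @field_validator("kappa")
    @classmethod
    def _ge_one(cls, v):
        if v < 1.0:
            raise ValueError("routing.kappa must be >= 1")
        return v


class CohortConfig(BaseModel):
    """Everything the generator needs for one cohort.

    ``junction_strategy`` selects how break probabilities are calibrated:

    * ``per_size`` — each size class gets its own per-junction probability,
      inverted from the per-size dissociation frequencies (pooled-geometry
      calibration).
    * ``per_geometry`` — one per-junction probability for the whole cohort,
      inverted from the device arm's all-cluster dissociation frequency
      under the cohort size mix (``geometry_arm`` defaults to the device
      code if calibrated, else the pooled equal/unequal arm).
    """

    n_clusters: int = 10000
    n_singles: int = 0
    device_code: str = "ENA_7/7"
    size_pmf: dict[str, float] = Field(
        default_factory=lambda: {"2": 0.76, "3": 0.16, "4+": 0.08}
    )
    tail: TailConfig = Field(default_factory=TailConfig)
    junction_strategy: Literal["per_size", "per_geometry"] = "per_size"
    geometry_arm: str | None = None
    per_size_dissociation: dict[str, float] = Field(
        default_factory=lambda: {"2": 0.51, "3": 0.67, "4+": 0.91}
    )
    per_geometry_dissociation: dict[str, float] = Field(default_factory=dict)
    cytod_dissociation: dict[str, dict[str, float]] = Field(default_factory=dict)
    treated: bool = False
    routing: RoutingConfig = Field(default_factory=RoutingConfig)
    death_probs: dict[str, float] = Field(default_factory=dict)
    volume_model: VolumeConfig = Field(default_factory=VolumeConfig)
    correlation_rho: float = 0.0
    lysis_mode: LysisMode = LysisMode.annotate
    shear_dissociation_rate: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_singles < 0:
            raise ValueError("n_singles must be >= 0")
        total = sum(self.size_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size_pmf must sum to 1, got {total}")
        for k, v in self.size_pmf.items():
            if k != "4+" and not k.isdigit():
                raise ValueError(f"size_pmf key must be an integer or '4+', got {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"size_pmf[{k!r}] must be in [0, 1]")
        for table_name in ("per_size_dissociation", "per_geometry_dissociation", "death_probs"):
            for k, v in getattr(self, table_name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{table_name}[{k!r}] must be in [0, 1]")
        if not 0.0 <= self.correlation_rho <= 1.0:
            raise ValueError("correlation_rho must be in [0, 1]")
        return self

    def device(self) -> BifurcationDevice:
        return get_device(self.device_code)


def default_config(**overrides) -> CohortConfig:
    """Cohort config pre-filled with the shipped calibration."""
    cal = load_default_calibration()
    base = dict(
        size_pmf=cal["size_mix"],
        tail=cal["tail"],
        per_size_dissociation=cal["per_size_dissociation"],
        per_geometry_dissociation=cal["per_geometry_dissociation"],
        cytod_dissociation=cal["cytod_dissociation"],
        death_probs=cal["death_probs"],
        volume_model=cal["volume_model"],
        routing=cal["routing"],
    )
    base.update(overrides)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# Size and volume sampling
# ---------------------------------------------------------------------------


def expected_size_distribution(config: CohortConfig) -> dict[int, float]:
    """Exact P(n_cells = s) implied by the class mix and the 4+ tail."""
    dist: dict[int, float] = {}
    tail_w = config.tail.weights()
    for cls, p in config.size_pmf.items():
        if p == 0:
            continue
        if cls == "4+":
            for s, w in tail_w.items():
                dist[s] = dist.get(s, 0.0) + p * w
        else:
            s = int(cls)
            dist[s] = dist.get(s, 0.0) + p
    return dict(sorted(dist.items()))


def sample_cluster_sizes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_clusters`` cluster sizes from the configured mix."""
    dist = expected_size_distribution(config)
    sizes = np.array(list(dist), dtype=int)
    probs = np.array([dist[s] for s in sizes])
    probs = probs / probs.sum()
    return rng.choice(sizes, size=config.n_clusters, p=probs)


def _capillary_key(device: BifurcationDevice, config: CohortConfig) -> str:
    """Pick the volume-model capillary class nearest the device's narrow
    daughter width (falls back to the parent width for controls)."""
    if device.bifurcating:
        width = device.daughter1.width_a
    else:
        width = device.parent.width_a
    keys = sorted(config.volume_model.cell_mean_pl, key=float)
    return min(keys, key=lambda k: abs(float(k) - width))


def sample_volumes(
    size: int,
    dissociating: bool,
    capillary: str | int,
    config: CohortConfig,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Total cytoplasmic cluster volume (pL), lognormal.

    The mean is ``size * cell_mean_pl[capillary]``, multiplied by the
    calibrated dissociating:intact ratio when ``dissociating``; the log-SD is
    ``sigma_log``. With ``sigma_log == 0`` the draw is the mean exactly.
    """
    vm = config.volume_model
    key = str(capillary)
    if key not in vm.cell_mean_pl:
        raise KeyError(f"no volume calibration for capillary {key!r}")
    mean = size * vm.cell_mean_pl[key]
    if dissociating:
        mean *= vm.dissociating_multiplier.get(key, 1.0)
    if vm.sigma_log == 0:
        return np.full(n, mean)
    mu = np.log(mean) - 0.5 * vm.sigma_log**2
    return rng.lognormal(mu, vm.sigma_log, size=n)


# ---------------------------------------------------------------------------
# Calibration inversion: arm frequencies -> per-junction probabilities
# ---------------------------------------------------------------------------


def invert_class_rate(target: float, size_dist: dict[int, float]) -> float:
    """Per-junction break probability p such that the expected dissociation
    frequency E_s[1 - (1-p)**(s-1)] over ``size_dist`` equals ``target``."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("target frequency must be in [0, 1]")
    if target == 0.0:
        return 0.0
    if target == 1.0:
        return 1.0
    sizes = np.array(list(size_dist), dtype=float)
    weights = np.array(list(size_dist.values()))
    weights = weights / weights.sum()
    n_junc = sizes - 1.0
    if (n_junc <= 0).all():
        raise ValueError("size distribution contains no clusters")

    def mean_rate(p: float) -> float:
        return float(np.sum(weights * (1.0 - (1.0 - p) ** n_junc)))

    return float(brentq(lambda p: mean_rate(p) - target, 0.0, 1.0, xtol=1e-12))


def _resolve_arm(config: CohortConfig, device: BifurcationDevice) -> str:
    if config.geometry_arm is not None:
        arm = config.geometry_arm
    elif device.code in config.per_geometry_dissociation:
        arm = device.code
    elif device.bifurcating and device.equality is not None:
        arm = f"{device.equality.value}_pooled"
    else:
        raise KeyError(f"no geometry arm calibrated for device {device.code!r}")
    if arm not in config.per_geometry_dissociation:
        raise KeyError(f"geometry arm {arm!r} missing from per_geometry_dissociation")
    return arm


def _cytod_target(config: CohortConfig, arm: str) -> float:
    entry = config.cytod_dissociation.get(arm)
    if entry is None:
        raise KeyError(f"no Cyto-D calibration for arm {arm!r}")
    doublets_only = config.size_pmf.get("2", 0.0) == 1.0
    if doublets_only and "doublets" in entry:
        return entry["doublets"]
    return entry["all"]


def make_junction_lookup(config: CohortConfig) -> transit.JunctionLookup:
    """Build the (device, n_cells, treated) -> p_break lookup for a config.

    Probabilities are precomputed by inverting the calibrated target
    frequencies; a missing calibration entry raises ``KeyError`` at build
    time, not mid-simulation.
    """
    tail_w = config.tail.weights()
    table: dict[tuple[str, bool], float] = {}

    if config.junction_strategy == "per_size":
        for cls, target in config.per_size_dissociation.items():
            if cls == "4+":
                p = invert_class_rate(target, tail_w)
            else:
                s = int(cls)
                p = invert_class_rate(target, {s: 1.0})
            table[(cls, False)] = p
            table[(cls, True)] = p  # treatment not calibrated per size

        def lookup(device: BifurcationDevice, n_cells: int, treated: bool) -> float:
            from .estimation import size_class

            cls = size_class(n_cells)
            if cls == "1":
                return 0.0
            try:
                return table[(cls, treated)]
            except KeyError:
                raise KeyError(f"no per-size calibration for size class {cls!r}") from None

        return lookup

    # per_geometry: one probability for the whole cohort, from the arm mean
    device = config.device()
    arm = _resolve_arm(config, device)
    size_dist = expected_size_distribution(config)
    p_untreated = invert_class_rate(config.per_geometry_dissociation[arm], size_dist)
    p_treated = p_untreated
    if config.treated or arm in config.cytod_dissociation:
        if arm in config.cytod_dissociation:
            p_treated = invert_class_rate(_cytod_target(config, arm), size_dist)
        elif config.treated:
            raise KeyError(f"treated cohort but no Cyto-D calibration for arm {arm!r}")

    def lookup(device: BifurcationDevice, n_cells: int, treated: bool) -> float:
        if n_cells < 2:
            return 0.0
        return p_treated if treated else p_untreated

    return lookup


def make_lysis_lookup(config: CohortConfig) -> transit.LysisLookup | None:
    if not config.death_probs:
        return None

    def lookup(condition: str) -> float:
        try:
            return config.death_probs[condition]
        except KeyError:
            raise KeyError(
                f"no death probability configured for condition {condition!r}"
            ) from None

    return lookup


def different_branch_closed_form(kappa: float, config: CohortConfig) -> float:
    """Exact probability that a dissociating cluster's fragments exit via
    different branches of an *equal* bifurcation under occlusion-aware
    routing.

    With the bare split at 0.5, consecutive fragments land in different
    branches with probability ``kappa / (kappa + 1)``, so a cluster with
    ``k`` broken junctions keeps all fragments in one branch with
    probability ``(kappa + 1)**-k``. The mixture over ``k`` uses the
    config's size mix and per-size break calibration, conditioned on at
    least one break.
    """
    from scipy.stats import binom

    device = config.device()
    lookup = make_junction_lookup(config)
    c = 1.0 / (kappa + 1.0)
    num = den = 0.0
    for s, ws in expected_size_distribution(config).items():
        p = lookup(device, s, config.treated)
        n_j = s - 1
        for k in range(1, n_j + 1):
            pk = float(binom.pmf(k, n_j, p))
            num += ws * pk * c**k
            den += ws * pk
    if den == 0:
        raise ValueError("no dissociation possible under this configuration")
    return 1.0 - num / den


def calibrate_kappa(config: CohortConfig | None = None, target: float = 0.88) -> float:
    """Occlusion factor that makes :func:`different_branch_closed_form`
    equal ``target`` under the given (default) cohort configuration."""
    if config is None:
        config = default_config()
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    return float(
        brentq(lambda k: different_branch_closed_form(k, config) - target, 1.0, 1e4, xtol=1e-10)
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _cluster_rng(seed: int, index: int) -> np.random.Generator:
    # Substream keyed on (seed, index): stable under cohort-size changes.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[ClusterState], pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort and its event + viability tables.

    Returns ``(clusters, events, viability)``; when ``out_dir`` is given,
    also writes ``events.csv`` and ``viability.csv`` there. Fully
    deterministic given ``config.seed``.
    """
    device = config.device()
    junction_lookup = make_junction_lookup(config)
    lysis_lookup = make_lysis_lookup(config)
    cap = _capillary_key(device, config)

    sizes = sample_cluster_sizes(config, _cluster_rng(config.seed, 0))
    events: list[TransitEvent] = []
    for i, size in enumerate(sizes):
        rng = _cluster_rng(config.seed, i + 1)
        cluster = ClusterState(cluster_id=f"c{i:06d}", n_cells=int(size), treated=config.treated)
        ev = simulate_cohort(
            [cluster],
            device,
            junction_lookup,
            lysis_lookup,
            rng,
            routing_mode=config.routing.mode,
            kappa=config.routing.kappa,
            correlation_rho=config.correlation_rho,
            lysis_mode=config.lysis_mode,
            shear_dissociation_rate=config.shear_dissociation_rate,
        )[0]
        ev.volume_pl = float(
            sample_volumes(int(size), ev.dissociated, cap, config, rng, n=1)[0]
        )
        events.append(ev)
    for j in range(config.n_singles):
        rng = _cluster_rng(config.seed, len(sizes) + 1 + j)
        single = ClusterState(cluster_id=f"s{j:06d}", n_cells=1, treated=config.treated)
        events.append(
            simulate_cohort(
                [single],
                device,
                junction_lookup,
                lysis_lookup,
                rng,
                routing_mode=config.routing.mode,
                kappa=config.routing.kappa,
                lysis_mode=config.lysis_mode,
            )[0]
        )

    events_df = events_to_frame(events, seed=config.seed)
    via_rows = []
    for ev in events:
        cond = lysis_condition(device, ev.n_cells_in >= 2, ev.treated)
        for ci, dead in enumerate(ev.lysed_flags):
            via_rows.append(
                {
                    "cell_id": f"{ev.cluster_id}.{ci}",
                    "cluster_id": ev.cluster_id,
                    "condition": cond,
                    "dead": bool(dead),
                }
            )
    viability_df = pd.DataFrame(via_rows, columns=["cell_id", "cluster_id", "condition", "dead"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(out / "events.csv", index=False)
        viability_df.to_csv(out / "viability.csv", index=False)

    clusters = [
        ClusterState(cluster_id=f"c{i:06d}", n_cells=int(s), treated=config.treated)
        for i, s in enumerate(sizes)
    ]
    return clusters, events_df, viability_df
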