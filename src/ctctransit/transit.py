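"""Stochastic single-file transit of tumor-cell clusters through bifurcations.

A cluster of ``n`` cells squeezing through a capillary-scale constriction
unfolds into a single file, so it carries exactly ``n - 1`` cell-cell
junctions. At a bifurcation each junction breaks with probability ``p_break``,
independently of the others under the default model, so the probability that
a cluster experiences at least one dissociation event is

    P(at least one) = 1 - (1 - p_break)**(n - 1).

Broken junctions partition the file into fragments (smaller clusters and
single cells), which are then routed into the daughter branches by the
laminar flow split, optionally with a transient occlusion effect: a fragment
occupying a branch raises that branch's resistance for the fragment behind
it, which biases consecutive fragments into different branches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import BifurcationDevice, device_flow_split

__all__ = [
    "ClusterState",
    "JunctionModel",
    "TransitEvent",
    "RoutingMode",
    "LysisMode",
    "p_at_least_one",
    "sample_breaks",
    "fragments_from_breaks",
    "fragment_size_pmf",
    "route_fragments",
    "simulate_cohort",
    "simulate_cascade",
    "events_to_frame",
    "events_to_csv",
    "events_from_csv",
    "DEFAULT_KAPPA",
]

#: Occlusion factor: multiplier on the occupied branch's resistance seen by
#: the next fragment. In an equal bifurcation consecutive fragments then
#: land in different branches with probability kappa/(kappa+1). The default
#: solves the closed-form mixed-cohort equation so that, under the shipped
#: size mix and per-size break calibration, 88% of dissociating clusters
#: have fragments in different branches — the observed rate. See
#: :func:`ctctransit.synthetic.calibrate_kappa`.
DEFAULT_KAPPA = 6.295840735330156

#: Flow-split threshold above which the larger branch captures every
#: fragment deterministically (strongly unequal daughter branches).
CAPTURE_SPLIT = 0.9


class RoutingMode(str, Enum):
    independent_flow_split = "independent_flow_split"
    occlusion_alternating = "occlusion_alternating"


class LysisMode(str, Enum):
    annotate = "annotate"  # lysed cells stay in reported fragment sizes
    remove = "remove"  # lysed cells are deleted from fragments


@dataclass
class ClusterState:
    """One cluster about to transit, in single-file order."""

    cluster_id: str
    n_cells: int
    cell_volumes: list[float] | None = None
    treated: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_volumes is not None and len(self.cell_volumes) != self.n_cells:
            raise ValueError("cell_volumes length must equal n_cells")

    @property
    def is_cluster(self) -> bool:
        return self.n_cells >= 2

    @property
    def n_junctions(self) -> int:
        return self.n_cells - 1


@dataclass(frozen=True)
class JunctionModel:
    """Per-junction breakage model for one cluster.

    ``correlation_rho`` couples junction failures through a shared Gaussian
    frailty (0 = fully independent junctions, the default assumption;
    1 = all junctions of a cluster fail or hold together).
    """

    p_break: float
    n_junctions: int
    correlation_rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_break <= 1.0:
            raise ValueError("p_break must be in [0, 1]")
        if self.n_junctions < 0:
            raise ValueError("n_junctions must be >= 0")
        if not 0.0 <= self.correlation_rho <= 1.0:
            raise ValueError("correlation_rho must be in [0, 1]")


@dataclass
class TransitEvent:
    """One observed or simulated transit through a device."""

    cluster_id: str
    device_code: str
    n_cells_in: int
    fragment_sizes: list[int]
    fragment_branches: list[int]
    lysed_flags: list[bool]
    treated: bool = False
    transit_time_s: float | None = None
    volume_pl: float | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.fragment_sizes):
            raise ValueError("fragment sizes must be >= 1")
        if self.fragment_branches and len(self.fragment_branches) != len(self.fragment_sizes):
            raise ValueError("one branch assignment per fragment required")

    @property
    def dissociated(self) -> bool:
        return len(self.fragment_sizes) > 1

    @property
    def n_lysed(self) -> int:
        return int(sum(self.lysed_flags))


def p_at_least_one(p_break: float, n_junctions: int) -> float:
    """Probability of >= 1 junction failure among ``n_junctions`` independent
    junctions each breaking with probability ``p_break``."""
    if not 0.0 <= p_break <= 1.0:
        raise ValueError("p_break must be in [0, 1]")
    if n_junctions < 0:
        raise ValueError("n_junctions must be >= 0")
    return 1.0 - (1.0 - p_break) ** n_junctions


def sample_breaks(model: JunctionModel, rng: np.random.Generator) -> frozenset[int]:
    """Sample the set of broken junctions (1-based indices).

    Junction ``i`` sits between cells ``i`` and ``i + 1`` of the single file.
    With ``correlation_rho == 0`` junctions fail independently; otherwise a
    Gaussian-copula shared frailty couples them while keeping the marginal
    failure probability exactly ``p_break``.
    """
    n = model.n_junctions
    if n == 0:
        return frozenset()
    rho = model.correlation_rho
    if rho == 0.0:
        u = rng.random(n)
    else:
        z_shared = rng.standard_normal()
        z_own = rng.standard_normal(n)
        z = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_own
        u = norm.cdf(z)
    return frozenset(int(i) + 1 for i in np.nonzero(u < model.p_break)[0])


def fragments_from_breaks(n_cells: int, break_pattern: Iterable[int]) -> list[int]:
    """Fragment sizes produced by a set of broken junctions.

    Fragments are the maximal runs of the single-file chain between broken
    junctions, in transit order; sizes sum to ``n_cells``.
    """
    breaks = sorted(set(break_pattern))
    if breaks and (breaks[0] < 1 or breaks[-1] > n_cells - 1):
        raise ValueError(f"junction indices must lie in 1..{n_cells - 1}")
    cuts = [0, *breaks, n_cells]
    return [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]


def fragment_size_pmf(n_cells: int, p_break: float) -> dict[tuple[int, ...], float]:
    """Exact distribution of the (ordered) fragment-size tuple for a cluster
    of ``n_cells`` under independent junction failure.

    Enumerates all 2**(n-1) break patterns; intended for small ``n``.
    """
    pmf: dict[tuple[int, ...], float] = {}
    n_j = n_cells - 1
    for pattern in itertools.product([0, 1], repeat=n_j):
        breaks = [i + 1 for i, b in enumerate(pattern) if b]
        k = len(breaks)
        prob = p_break**k * (1.0 - p_break) ** (n_j - k)
        sizes = tuple(fragments_from_breaks(n_cells, breaks))
        pmf[sizes] = pmf.get(sizes, 0.0) + prob
    return pmf


def route_fragments(
    fragments: Sequence[int],
    device: BifurcationDevice,
    mode: RoutingMode | str = RoutingMode.occlusion_alternating,
    rng: np.random.Generator | None = None,
    kappa: float = DEFAULT_KAPPA,
) -> list[int]:
    """Assign each fragment (in transit order) to daughter branch 1 or 2.

    ``independent_flow_split``: every fragment independently enters branch 2
    with probability f2 = R1/(R1+R2).

    ``occlusion_alternating``: the leading fragment follows the bare flow
    split; each subsequent fragment sees the branch occupied by the fragment
    ahead of it with its resistance multiplied by ``kappa`` >= 1, biasing it
    into the free branch.

    When the bare split is strongly unequal (f2 >= 0.9) every fragment is
    captured by the larger branch under both modes.
    """
    if not device.bifurcating:
        raise ValueError(f"device {device.code} does not bifurcate; cannot route")
    mode = RoutingMode(mode)
    if kappa < 1.0:
        raise ValueError("kappa must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    f2 = device_flow_split(device)
    if f2 >= CAPTURE_SPLIT:
        return [2] * len(fragments)
    if mode is RoutingMode.independent_flow_split:
        return [2 if rng.random() < f2 else 1 for _ in fragments]
    # occlusion_alternating
    branches: list[int] = []
    r1 = f2  # bare R1 up to a common factor: f2 = R1/(R1+R2)
    r2 = 1.0 - f2
    for i, _ in enumerate(fragments):
        if not branches:
            eff_f2 = f2
        else:
            occupied = branches[-1]
            e1 = r1 * (kappa if occupied == 1 else 1.0)
            e2 = r2 * (kappa if occupied == 2 else 1.0)
            eff_f2 = e1 / (e1 + e2)
        branches.append(2 if rng.random() < eff_f2 else 1)
    return branches


JunctionLookup = Callable[[BifurcationDevice, int, bool], float]
LysisLookup = Callable[[str], float]


def lysis_condition(device: BifurcationDevice, is_cluster: bool, treated: bool) -> str:
    """Canonical condition label for per-cell death probabilities."""
    geom = "bifurcation" if device.bifurcating else (
        "linear" if device.constricted else "nonconstricted"
    )
    unit = "cluster" if is_cluster else "single"
    arm = "cytod" if treated else "untreated"
    return f"{geom}_{unit}_{arm}"


def _transit_one(
    cluster: ClusterState,
    device: BifurcationDevice,
    junction_lookup: JunctionLookup,
    lysis_lookup: LysisLookup | None,
    rng: np.random.Generator,
    *,
    routing_mode: RoutingMode | str,
    kappa: float,
    correlation_rho: float,
    lysis_mode: LysisMode | str,
    shear_dissociation_rate: float,
) -> TransitEvent:
    n = cluster.n_cells
    if device.constricted:
        p = junction_lookup(device, n, cluster.treated)
    else:
        # Nonconstricted control: no single-file constriction, only an
        # optional shear-driven junction failure rate.
        p = shear_dissociation_rate
    model = JunctionModel(p_break=p, n_junctions=n - 1, correlation_rho=correlation_rho)
    breaks = sample_breaks(model, rng)
    fragments = fragments_from_breaks(n, breaks)
    if device.bifurcating:
        branches = route_fragments(fragments, device, routing_mode, rng, kappa)
    else:
        branches = []

    lysed: list[bool] = [False] * n
    if lysis_lookup is not None:
        death_p = lysis_lookup(lysis_condition(device, cluster.is_cluster, cluster.treated))
        lysed = list(rng.random(n) < death_p)

    if LysisMode(lysis_mode) is LysisMode.remove and any(lysed):
        kept_sizes: list[int] = []
        kept_branches: list[int] = []
        cell = 0
        for j, size in enumerate(fragments):
            alive = sum(1 for c in range(cell, cell + size) if not lysed[c])
            cell += size
            if alive > 0:
                kept_sizes.append(alive)
                if branches:
                    kept_branches.append(branches[j])
        fragments, branches = kept_sizes, kept_branches

    return TransitEvent(
        cluster_id=cluster.cluster_id,
        device_code=device.code,
        n_cells_in=n,
        fragment_sizes=fragments,
        fragment_branches=branches,
        lysed_flags=lysed,
        treated=cluster.treated,
        volume_pl=(sum(cluster.cell_volumes) if cluster.cell_volumes else None),
    )


def simulate_cohort(
    clusters: Iterable[ClusterState],
    device: BifurcationDevice,
    junction_lookup: JunctionLookup,
    lysis_lookup: LysisLookup | None,
    rng: np.random.Generator,
    *,
    routing_mode: RoutingMode | str = RoutingMode.occlusion_alternating,
    kappa: float = DEFAULT_KAPPA,
    correlation_rho: float = 0.0,
    lysis_mode: LysisMode | str = LysisMode.annotate,
    shear_dissociation_rate: float = 0.0,
) -> list[TransitEvent]:
    """Simulate one transit per cluster through ``device``.

    ``junction_lookup(device, n_cells, treated)`` supplies the per-junction
    break probability; ``lysis_lookup(condition)`` the per-cell death
    probability (pass ``None`` to disable lysis). Draws come exclusively from
    ``rng``, so a seeded generator makes the cohort fully reproducible.
    """
    return [
        _transit_one(
            c,
            device,
            junction_lookup,
            lysis_lookup,
            rng,
            routing_mode=routing_mode,
            kappa=kappa,
            correlation_rho=correlation_rho,
            lysis_mode=lysis_mode,
            shear_dissociation_rate=shear_dissociation_rate,
        )
        for c in clusters
    ]


def simulate_cascade(
    clusters: Sequence[ClusterState],
    devices: Sequence[BifurcationDevice],
    junction_lookup: JunctionLookup,
    lysis_lookup: LysisLookup | None,
    rng: np.random.Generator,
    **kwargs,
) -> list[list[TransitEvent]]:
    """Transit a cohort through an ordered cascade of bifurcations.

    Fragments leaving level ``k`` transit level ``k + 1`` as independent
    units (each fragment, including single cells, becomes its own transit).
    Returns one event list per level. Total cell count is conserved across
    levels (up to lysed-cell removal when ``lysis_mode='remove'``), and the
    largest fragment size is non-increasing level over level.
    """
    if not devices:
        raise ValueError("cascade requires at least one device")
    levels: list[list[TransitEvent]] = []
    current = list(clusters)
    for li, device in enumerate(devices):
        events = simulate_cohort(current, device, junction_lookup, lysis_lookup, rng, **kwargs)
        levels.append(events)
        nxt: list[ClusterState] = []
        for ev in events:
            for fi, size in enumerate(ev.fragment_sizes):
                nxt.append(
                    ClusterState(
                        cluster_id=f"{ev.cluster_id}/L{li + 1}F{fi}",
                        n_cells=size,
                        treated=ev.treated,
                    )
                )
        current = nxt
    return levels


# ---------------------------------------------------------------------------
# Event-table I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "cluster_id",
    "device_code",
    "n_cells_in",
    "fragment_sizes",
    "fragment_branches",
    "n_lysed",
    "dissociated",
    "treated",
    "seed",
]


def events_to_frame(events: Iterable[TransitEvent], seed: int | None = None) -> pd.DataFrame:
    """Flatten transit events into the canonical event table.

    List-valued fields are semicolon-joined; ``volume_pl`` is carried as an
    optional extra column when any event has one.
    """
    rows = []
    any_volume = False
    for ev in events:
        rows.append(
            {
                "cluster_id": ev.cluster_id,
                "device_code": ev.device_code,
                "n_cells_in": ev.n_cells_in,
                "fragment_sizes": ";".join(map(str, ev.fragment_sizes)),
                "fragment_branches": ";".join(map(str, ev.fragment_branches)),
                "n_lysed": ev.n_lysed,
                "dissociated": ev.dissociated,
                "treated": ev.treated,
                "seed": seed,
                "volume_pl": ev.volume_pl,
            }
        )
        any_volume = any_volume or ev.volume_pl is not None
    cols = _EVENT_COLUMNS + (["volume_pl"] if any_volume else [])
    return pd.DataFrame(rows, columns=cols)


def events_to_csv(events: Iterable[TransitEvent], path: str | Path, seed: int | None = None) -> None:
    events_to_frame(events, seed=seed).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> pd.DataFrame:
    """Read an event table, restoring integer/bool dtypes."""
    df = pd.read_csv(
        path,
        dtype={"fragment_sizes": str, "fragment_branches": str},
        keep_default_na=True,
    )
    df["fragment_sizes"] = df["fragment_sizes"].fillna("")
    df["fragment_branches"] = df["fragment_branches"].fillna("")
    for col in ("dissociated", "treated"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    return df
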