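"""Analysis pipeline for cluster-transit event tables.

Given an event table (one row per transiting cluster, with fragment sizes and
branch assignments), this module estimates:

* dissociation frequencies per group (size class, device, treatment arm) with
  Wilson 95% intervals,
* the per-junction break probability ``p`` by maximum likelihood under the
  independent-junction model, where a cluster of ``n`` cells dissociates with
  probability ``1 - (1 - p)**(n-1)``,
* predicted-vs-observed dissociation tables across size classes,
* branch-pathing preferences and the fraction of dissociating clusters whose
  fragments exit via different daughter branches,
* cohort composition (mean cells per cluster, cluster:single ratio) before
  and after transit, and per-cell viability summaries.

Significance testing is deliberately out of scope: reports carry point
estimates, intervals and fold changes only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EstimateReport",
    "size_class",
    "add_size_class",
    "dissociation_frequency",
    "fit_junction_probability",
    "predicted_table",
    "pathing_preference",
    "different_branch_fraction",
    "unit_sizes",
    "composition_summary",
    "fold_change",
    "viability_summary",
    "build_report",
]

_P_CLAMP = (1e-9, 1.0 - 1e-9)


def size_class(n_cells: int) -> str:
    """Bin a cell count into the reporting classes: '2', '3', '4+' ('1' for
    single cells, which are not clusters)."""
    if n_cells < 2:
        return "1"
    if n_cells >= 4:
        return "4+"
    return str(int(n_cells))


def add_size_class(events: pd.DataFrame) -> pd.DataFrame:
    out = events.copy()
    out["size_class"] = out["n_cells_in"].map(size_class)
    return out


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def dissociation_frequency(
    events: pd.DataFrame, group_by: str | Sequence[str] = "size_class"
) -> pd.DataFrame:
    """Dissociation frequency per group: dissociating clusters / transiting
    clusters, with Wilson 95% intervals.

    Rows with ``n_cells_in < 2`` (single cells) are excluded — a single cell
    has no junction to break. Empty groups simply do not appear (missing,
    never zero).
    """
    df = add_size_class(events)
    df = df[df["n_cells_in"] >= 2]
    if df.empty:
        raise ValueError("no clusters (n_cells_in >= 2) in event table")
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    records = []
    for name, g in df.groupby(keys, sort=True):
        k = int(g["dissociated"].sum())
        n = len(g)
        lo, hi = _wilson(k, n)
        rec = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        rec.update(frequency=k / n, ci_low=lo, ci_high=hi, n=n, n_dissociated=k)
        records.append(rec)
    return pd.DataFrame(records)


def _loglik(p: float, n_junc: np.ndarray, y: np.ndarray) -> float:
    q = 1.0 - p
    qn = q**n_junc
    with np.errstate(divide="ignore"):
        ll = np.where(y == 1, np.log1p(-qn), n_junc * np.log(q))
    return float(ll.sum())


def _score(p: float, n_junc: np.ndarray, y: np.ndarray) -> float:
    # d/dp of the log-likelihood: broken clusters pull p up, intact pull down
    q = 1.0 - p
    qn = q**n_junc
    up = np.where(y == 1, n_junc * qn / (q * (1.0 - qn)), 0.0)
    down = np.where(y == 0, n_junc / q, 0.0)
    return float(up.sum() - down.sum())


def fit_junction_probability(events: pd.DataFrame) -> tuple[float, float]:
    """Maximum-likelihood per-junction break probability from an event table.

    A cluster with ``n`` cells contributes a Bernoulli observation with
    success probability ``1 - (1-p)**(n-1)``. For doublet-only data the MLE
    is the sample dissociation proportion exactly. Returns ``(p_hat, se)``
    with the standard error from observed Fisher information (p clamped away
    from the boundary for the curvature evaluation).
    """
    df = events[events["n_cells_in"] >= 2]
    if df.empty:
        raise ValueError("junction probability requires clusters (n_cells_in >= 2)")
    n_junc = df["n_cells_in"].to_numpy(dtype=float) - 1.0
    y = df["dissociated"].to_numpy(dtype=int)

    if y.all():
        p_hat = 1.0
    elif not y.any():
        p_hat = 0.0
    elif np.all(n_junc == 1):
        p_hat = float(y.mean())
    else:
        p_hat = float(brentq(_score, 1e-12, 1.0 - 1e-12, args=(n_junc, y), xtol=1e-12))

    pc = min(max(p_hat, _P_CLAMP[0]), _P_CLAMP[1])
    h = 1e-5
    lo = max(pc - h, _P_CLAMP[0])
    hi = min(pc + h, _P_CLAMP[1])
    d2 = (_loglik(hi, n_junc, y) - 2.0 * _loglik(pc, n_junc, y) + _loglik(lo, n_junc, y)) / (
        ((hi - lo) / 2.0) ** 2
    )
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("inf")
    return p_hat, se


def predicted_table(
    p_hat: float,
    observed: pd.DataFrame | None = None,
    max_junctions: int = 3,
) -> pd.DataFrame:
    """Predicted dissociation frequency per junction count under the
    independent-junction model, optionally joined with observed per-class
    frequencies (from :func:`dissociation_frequency` grouped by size class).

    Junction counts 1, 2, 3 correspond to doublets, triplets, quadruplets.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    rows = []
    for n_j in range(1, max_junctions + 1):
        cls = size_class(n_j + 1)
        rows.append(
            {
                "size_class": cls,
                "n_junctions": n_j,
                "predicted": 1.0 - (1.0 - p_hat) ** n_j,
            }
        )
    table = pd.DataFrame(rows)
    if observed is not None and "size_class" in observed.columns:
        obs = observed.set_index("size_class")["frequency"]
        table["observed"] = table["size_class"].map(obs)
    return table


def _branch_units(events: pd.DataFrame) -> pd.DataFrame:
    """Explode an event table into one row per transiting unit (fragment)."""
    df = events[events["fragment_branches"].astype(str).str.len() > 0].copy()
    units = []
    for _, row in df.iterrows():
        sizes = [int(s) for s in str(row["fragment_sizes"]).split(";") if s]
        branches = [int(b) for b in str(row["fragment_branches"]).split(";") if b]
        for s, b in zip(sizes, branches):
            units.append(
                {
                    "cluster_id": row["cluster_id"],
                    "device_code": row["device_code"],
                    "size": s,
                    "branch": b,
                }
            )
    return pd.DataFrame(units)


def pathing_preference(
    events: pd.DataFrame, group_by: str | Sequence[str] = "device_code"
) -> pd.DataFrame:
    """Fraction of transiting units exiting via daughter branch 2 (by
    convention the wider branch), per group.

    Rows without branch assignments (non-bifurcating devices) are excluded;
    the number excluded is reported in the ``n_excluded`` attribute of the
    returned frame.
    """
    n_excluded = int((events["fragment_branches"].astype(str).str.len() == 0).sum())
    units = _branch_units(events)
    if units.empty:
        raise ValueError("no branch assignments present (non-bifurcating events only?)")
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    merged = units.merge(
        add_size_class(events)[["cluster_id", "device_code", "treated", "size_class"]].drop_duplicates(
            "cluster_id"
        ),
        on=["cluster_id", "device_code"],
        how="left",
    )
    records = []
    for name, g in merged.groupby(keys, sort=True):
        k = int((g["branch"] == 2).sum())
        n = len(g)
        lo, hi = _wilson(k, n)
        rec = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        rec.update(fraction_d2=k / n, ci_low=lo, ci_high=hi, n=n)
        records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["n_excluded"] = n_excluded
    return out


def different_branch_fraction(events: pd.DataFrame) -> tuple[float, int]:
    """Among dissociating clusters with branch assignments, the fraction
    whose fragments did not all exit via the same branch.

    Returns ``(fraction, n_dissociating)``.
    """
    df = events[
        events["dissociated"] & (events["fragment_branches"].astype(str).str.len() > 0)
    ]
    if df.empty:
        raise ValueError("no dissociating events with branch assignments")
    split = df["fragment_branches"].astype(str).map(lambda s: len(set(s.split(";"))) > 1)
    return float(split.mean()), len(df)


def unit_sizes(events: pd.DataFrame, stage: str) -> list[int]:
    """Cell counts of transiting units: input clusters (``stage='pre'``) or
    output fragments (``stage='post'``)."""
    if stage == "pre":
        return [int(n) for n in events["n_cells_in"]]
    if stage == "post":
        sizes: list[int] = []
        for s in events["fragment_sizes"].astype(str):
            sizes.extend(int(x) for x in s.split(";") if x)
        return sizes
    raise ValueError("stage must be 'pre' or 'post'")


def _composition(sizes: Sequence[int]) -> dict:
    arr = np.asarray(sizes, dtype=float)
    clusters = arr[arr >= 2]
    singles = arr[arr == 1]
    return {
        "mean_cells_per_cluster": float(clusters.mean()) if clusters.size else float("nan"),
        "sd_cells_per_cluster": float(clusters.std(ddof=1)) if clusters.size > 1 else 0.0,
        "max_cells": int(arr.max()) if arr.size else 0,
        "n_clusters": int(clusters.size),
        "n_singles": int(singles.size),
        "cluster_single_ratio": float(clusters.size / singles.size)
        if singles.size
        else float("inf"),
    }


def composition_summary(pre_events: pd.DataFrame, post_events: pd.DataFrame) -> dict:
    """Cohort composition before vs after transit.

    'Before' counts input clusters; 'after' counts output fragments. With no
    dissociation the two are identical.
    """
    if pre_events.empty or post_events.empty:
        raise ValueError("composition requires nonempty pre and post tables")
    return {
        "pre": _composition(unit_sizes(pre_events, "pre")),
        "post": _composition(unit_sizes(post_events, "post")),
    }


def fold_change(mean_a: float, mean_b: float, rounding: str | None = None) -> float:
    """Ratio ``mean_a / mean_b`` with report-style rounding.

    ``rounding``: None (raw), ``'1dp'`` (one decimal), ``'int'`` (nearest
    integer).
    """
    if mean_b == 0:
        raise ZeroDivisionError("fold change undefined for zero denominator")
    ratio = mean_a / mean_b
    if rounding is None:
        return ratio
    if rounding == "1dp":
        return round(ratio, 1)
    if rounding == "int":
        return float(round(ratio))
    raise ValueError("rounding must be None, '1dp' or 'int'")


def viability_summary(cells: pd.DataFrame, conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-condition death fraction with Wilson 95% intervals.

    ``cells`` has one row per cell with columns ``condition`` and ``dead``.
    If ``conditions`` is given, any label outside it raises.
    """
    if conditions is not None:
        unknown = set(cells["condition"]) - set(conditions)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    records = []
    for cond, g in cells.groupby("condition", sort=True):
        k = int(g["dead"].sum())
        n = len(g)
        lo, hi = _wilson(k, n)
        records.append(
            {"condition": cond, "death_fraction": k / n, "ci_low": lo, "ci_high": hi, "n": n}
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EstimateReport:
    """Bundle of pipeline outputs with JSON / Markdown rendering.

    Frequencies are stored as fractions and rendered as percentages with one
    decimal.
    """

    per_size_freq: pd.DataFrame
    p_hat: float
    p_hat_se: float
    predicted_vs_observed: pd.DataFrame
    pathing: pd.DataFrame | None = None
    different_branch: tuple[float, int] | None = None
    composition: dict | None = None
    viability: pd.DataFrame | None = None
    fold_changes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "per_size_freq": self.per_size_freq.to_dict(orient="records"),
            "p_hat": self.p_hat,
            "p_hat_se": self.p_hat_se,
            "predicted_vs_observed": self.predicted_vs_observed.to_dict(orient="records"),
            "fold_changes": self.fold_changes,
        }
        if self.pathing is not None:
            out["pathing"] = self.pathing.to_dict(orient="records")
        if self.different_branch is not None:
            out["different_branch_fraction"] = self.different_branch[0]
            out["different_branch_n"] = self.different_branch[1]
        if self.composition is not None:
            out["composition"] = self.composition
        if self.viability is not None:
            out["viability"] = self.viability.to_dict(orient="records")
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")

    def to_markdown(self) -> str:
        pct = lambda x: f"{100.0 * x:.1f}%"  # noqa: E731
        lines = ["# Transit estimate report", "", "## Dissociation frequency by size class", ""]
        for _, r in self.per_size_freq.iterrows():
            lines.append(
                f"- {r['size_class']}-cell: {pct(r['frequency'])} "
                f"(95% CI {pct(r['ci_low'])}-{pct(r['ci_high'])}, n={int(r['n'])})"
            )
        lines += [
            "",
            f"## Per-junction break probability (MLE): {self.p_hat:.4f} "
            f"(SE {self.p_hat_se:.4f})",
            "",
            "## Predicted vs observed",
            "",
        ]
        for _, r in self.predicted_vs_observed.iterrows():
            obs = pct(r["observed"]) if "observed" in r and pd.notna(r.get("observed")) else "-"
            lines.append(
                f"- {r['size_class']} ({int(r['n_junctions'])} junction(s)): "
                f"predicted {pct(r['predicted'])}, observed {obs}"
            )
        if self.different_branch is not None:
            frac, n = self.different_branch
            lines += ["", f"## Different-branch fragments: {pct(frac)} of {n} dissociating clusters"]
        if self.composition is not None:
            pre, post = self.composition["pre"], self.composition["post"]
            lines += [
                "",
                "## Composition (pre -> post)",
                f"- mean cells/cluster: {pre['mean_cells_per_cluster']:.2f} -> "
                f"{post['mean_cells_per_cluster']:.2f}",
                f"- max cells: {pre['max_cells']} -> {post['max_cells']}",
                f"- cluster:single ratio: {pre['cluster_single_ratio']:.2f} -> "
                f"{post['cluster_single_ratio']:.2f}",
            ]
        if self.viability is not None:
            lines += ["", "## Cell death by condition", ""]
            for _, r in self.viability.iterrows():
                lines.append(f"- {r['condition']}: {pct(r['death_fraction'])} (n={int(r['n'])})")
        if self.fold_changes:
            lines += ["", "## Fold changes", ""]
            for name, v in self.fold_changes.items():
                lines.append(f"- {name}: {v:g}")
        return "\n".join(lines) + "\n"


def build_report(
    events: pd.DataFrame,
    viability_cells: pd.DataFrame | None = None,
    fold_changes: Mapping[str, float] | None = None,
) -> EstimateReport:
    """Run the full estimation pipeline on an event table."""
    freq = dissociation_frequency(events, "size_class")
    p_hat, se = fit_junction_probability(events)
    pred = predicted_table(p_hat, observed=freq)
    pathing = None
    diff = None
    if (events["fragment_branches"].astype(str).str.len() > 0).any():
        pathing = pathing_preference(events, "device_code")
        if (events["dissociated"] & (events["fragment_branches"].astype(str).str.len() > 0)).any():
            diff = different_branch_fraction(events)
    comp = composition_summary(events, events)
    via = viability_summary(viability_cells) if viability_cells is not None else None
    return EstimateReport(
        per_size_freq=freq,
        p_hat=p_hat,
        p_hat_se=se,
        predicted_vs_observed=pred,
        pathing=pathing,
        different_branch=diff,
        composition=comp,
        viability=via,
        fold_changes=dict(fold_changes or {}),
    )
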