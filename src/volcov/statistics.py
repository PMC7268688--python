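"""Repeatability and workflow-comparison statistics.

Three questions are answered here.  First, how repeatable are the volume
measurements: per-region intraclass correlation coefficients — ICC(2,1),
the two-way random-effects, absolute-agreement, single-measure form that is
standard for test–retest designs — plus Bland–Altman limits of agreement on
paired measurements.  Second, do the skull-stripping workflows produce
different volumes: a one-way ANOVA per region across workflow groups, with
significant regions counted at a raw α (Benjamini–Hochberg available by
flag).  Third, do the workflows produce different *networks*: the group
covariance network yields one metric value per workflow, not per subject,
so inference uses subject-label permutation — repeatedly swapping the paired
subject rows between two workflow tables and rebuilding both networks — to
build the null distribution of each metric-AUC difference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_data import VolumeTable
from .graph_metrics import NullModelConfig, metrics_over_range
from .network_construction import DEFAULT_SPARSITY_GRID, build_network

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "RegionComparison",
    "NetworkComparison",
    "icc",
    "icc_from_array",
    "bland_altman",
    "anova_per_region",
    "compare_network_metrics",
]

ICC_MODEL_TAG = "ICC(2,1): two-way random effects, absolute agreement, single measures"


@dataclass
class ICCResult:
    per_region: np.ndarray
    average: float
    model: str = ICC_MODEL_TAG
    region_names: list[str] = field(default_factory=list)
    degenerate_regions: list[str] = field(default_factory=list)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float


@dataclass
class RegionComparison:
    region_names: list[str]
    f_statistic: np.ndarray
    p_value: np.ndarray
    alpha: float = 0.05
    adjustment: str = "none"

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.p_value < self.alpha))

    @property
    def significant_regions(self) -> list[str]:
        return [
            name
            for name, p in zip(self.region_names, self.p_value)
            if p < self.alpha
        ]


@dataclass
class NetworkComparison:
    """Observed metric-AUC differences (a − b) and permutation p-values."""

    pair: tuple[str, str]
    observed: dict[str, float]
    p_value: dict[str, float]
    n_perm: int


def icc_from_array(Y: np.ndarray) -> np.ndarray:
    """ICC(2,1) per region from data shaped (subjects, measurements[, regions]).

    Implements the two-way mean-squares decomposition directly (rows =
    subjects, columns = measurements): with MSR, MSC, MSE the row, column and
    residual mean squares,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

    Regions with zero total variance are degenerate — perfect agreement on a
    constant — and report ICC 1 (callers flag them).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    n, k, _ = Y.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 measurements")
    grand = Y.mean(axis=(0, 1))
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum(axis=0) / (k - 1)
    resid = Y - row_means[:, None, :] - col_means[None, :, :] + grand
    mse = (resid**2).sum(axis=(0, 1)) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    total_var = Y.var(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(total_var > 0, (msr - mse) / denom, 1.0)
    return vals


def icc(tables: Sequence[VolumeTable]) -> ICCResult:
    """Per-region ICC(2,1) across repeated measurements of one cohort."""
    if len(tables) < 2:
        raise ValueError("ICC needs at least two repeated measurements")
    first = tables[0]
    for t in tables[1:]:
        if t.subject_ids != first.subject_ids or t.region_names != first.region_names:
            raise ValueError("repeated tables must share subjects and regions")
    Y = np.stack([t.values for t in tables], axis=1)  # (n, k, regions)
    vals = icc_from_array(Y)
    total_var = Y.var(axis=(0, 1))
    degenerate = [
        name for name, tv in zip(first.region_names, total_var) if tv == 0
    ]
    return ICCResult(
        per_region=vals,
        average=float(vals.mean()),
        region_names=list(first.region_names),
        degenerate_regions=degenerate,
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Limits of agreement between two paired measurement series.

    The limits are mean ± 1.96·SD of the differences (SD with n−1
    denominator); ``pct_within`` is the percentage of pairs falling inside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    lo = mean_diff - 1.96 * sd_diff
    hi = mean_diff + 1.96 * sd_diff
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    return BlandAltmanResult(mean_diff, sd_diff, lo, hi, within)


def whole_brain_volume(table: VolumeTable) -> np.ndarray:
    """Per-subject whole-brain volume, taken as the sum over the 64 regions.

    Whether "whole brain" should instead be an independent mask volume is
    ambiguous; the region sum is used and flagged here.
    """
    return table.values.sum(axis=1)


def anova_per_region(
    tables: Mapping[str, VolumeTable],
    alpha: float = 0.05,
    adjustment: str = "none",
) -> RegionComparison:
    """One-way ANOVA per region across the workflow groups."""
    if len(tables) < 2:
        raise ValueError("need at least two workflow tables")
    names = None
    groups = []
    for wf, t in tables.items():
        if names is None:
            names = t.region_names
        elif t.region_names != names:
            raise ValueError("workflow tables must share the region set")
        if t.n_subjects < 2:
            raise ValueError(f"workflow {wf!r} has fewer than 2 subjects")
        groups.append(t.values)
    f, p = sps.f_oneway(*groups, axis=0)
    f = np.nan_to_num(np.asarray(f, dtype=float), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p, dtype=float))
    if adjustment == "BH":
        p = sps.false_discovery_control(p, method="bh")
    elif adjustment != "none":
        raise ValueError("adjustment must be 'none' or 'BH'")
    return RegionComparison(
        region_names=list(names),
        f_statistic=f,
        p_value=p,
        alpha=alpha,
        adjustment=adjustment,
    )


_PERM_METRICS = ("cp", "lp", "eglob", "eloc")


def _metric_aucs(
    table: VolumeTable, sparsity_range, shrinkage, edge_rule
) -> dict[str, float]:
    net = build_network(table, sparsity_range, shrinkage, edge_rule)
    report = metrics_over_range(net, NullModelConfig(n_null=0))
    return {m: report.auc[m] for m in _PERM_METRICS}


def compare_network_metrics(
    tables: Mapping[str, VolumeTable],
    sparsity_range=DEFAULT_SPARSITY_GRID,
    shrinkage="auto",
    edge_rule: str = "positive",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[NetworkComparison]:
    """Permutation comparison of network-metric AUCs between workflow pairs.

    The covariance network is group-level, so each workflow contributes one
    AUC per metric.  For each pair the null distribution is built by
    randomly swapping the two workflow labels within each paired subject row
    and rebuilding both networks; the two-sided p-value is
    (1 + #{|null diff| ≥ |observed|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(tables) < 2:
        raise ValueError("need at least two workflow tables")
    wf_names = list(tables)
    subjects = tables[wf_names[0]].subject_ids
    for t in tables.values():
        if t.subject_ids != subjects:
            raise ValueError("workflow tables must share the subject rows (paired)")
    results = []
    for a, b in combinations(wf_names, 2):
        pair_key = zlib.crc32(f"{a}|{b}".encode())  # stable across processes
        rng = np.random.default_rng(np.random.SeedSequence((seed, pair_key)))
        auc_a = _metric_aucs(tables[a], sparsity_range, shrinkage, edge_rule)
        auc_b = _metric_aucs(tables[b], sparsity_range, shrinkage, edge_rule)
        observed = {m: auc_a[m] - auc_b[m] for m in _PERM_METRICS}
        exceed = {m: 0 for m in _PERM_METRICS}
        Xa, Xb = tables[a].values, tables[b].values
        for _ in range(n_perm):
            swap = rng.random(len(subjects)) < 0.5
            Pa = np.where(swap[:, None], Xb, Xa)
            Pb = np.where(swap[:, None], Xa, Xb)
            ta = VolumeTable(subjects, tables[a].region_names, Pa, workflow="perm_a")
            tb = VolumeTable(subjects, tables[b].region_names, Pb, workflow="perm_b")
            pa = _metric_aucs(ta, sparsity_range, shrinkage, edge_rule)
            pb = _metric_aucs(tb, sparsity_range, shrinkage, edge_rule)
            for m in _PERM_METRICS:
                if abs(pa[m] - pb[m]) >= abs(observed[m]):
                    exceed[m] += 1
        p = {m: (1 + exceed[m]) / (n_perm + 1) for m in _PERM_METRICS}
        results.append(NetworkComparison((a, b), observed, p, n_perm))
    return results
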