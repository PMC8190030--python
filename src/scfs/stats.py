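"""Condition-level rupture-force statistics and nonparametric comparisons.

Summaries mirror the reporting shape of the study design: per pairing x
treatment x velocity, the median with 25th/75th percentiles (linear
interpolation between order statistics) and a fixed-bin-width histogram.
Conditions are compared with the two-sample Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration of the permutation null for small
samples, a tie-corrected normal approximation otherwise.  Significance is
flagged with the study's star convention: ``*`` for p < 0.05 and ``**`` for
p < 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ConditionDataset
from .errors import DataError, InsufficientDataError

__all__ = [
    "ConditionSummary",
    "VelocitySeries",
    "ComparisonResult",
    "summarize",
    "velocity_trend",
    "wilcoxon_ranksum",
    "build_summary_table",
    "compare_treatments",
    "stars_for_p",
]

#: Exact enumeration is used when the number of rank assignments is at most
#: this; beyond it the tie-corrected normal approximation takes over.
_MAX_EXACT_COMBINATIONS = 200_000


@dataclass
class ConditionSummary:
    """Percentiles and histogram of one pooled rupture-force population."""

    condition_label: str
    treatment_label: str
    velocity_v: float
    n: int
    q25: float | None
    median: float | None
    q75: float | None
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_label,
            "treatment": self.treatment_label,
            "velocity_um_per_s": self.velocity_v,
            "n": self.n,
            "q25_pN": self.q25,
            "median_pN": self.median,
            "q75_pN": self.q75,
            "bin_edges_pN": [float(b) for b in self.bin_edges],
            "counts": [int(c) for c in self.counts],
        }


@dataclass
class VelocitySeries:
    """Median rupture force versus pulling velocity with trend statistics."""

    velocities: np.ndarray
    medians: np.ndarray
    slope: float
    intercept: float
    spearman_rho: float


@dataclass
class ComparisonResult:
    """Mann-Whitney comparison of two force populations."""

    label_a: str
    label_b: str
    u_statistic: float
    p_value: float
    method: str

    @property
    def stars(self) -> str:
        return stars_for_p(self.p_value)


def stars_for_p(p: float) -> str:
    """Study star convention: ``**`` below 0.005, ``*`` below 0.05."""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(data: ConditionDataset, bin_width: float = 10.0) -> ConditionSummary:
    """Percentiles and histogram of a pooled condition dataset.

    Percentiles use linear interpolation between closest order statistics.
    The histogram covers [0, max] with fixed ``bin_width`` (pN).  An empty
    dataset yields the n=0 sentinel summary with no quantiles, which models
    the calcium-depleted regime.
    """
    forces = np.asarray(data.rupture_forces, dtype=float)
    if forces.size == 0:
        return ConditionSummary(
            condition_label=data.condition_label,
            treatment_label=data.treatment_label,
            velocity_v=data.velocity_v,
            n=0,
            q25=None,
            median=None,
            q75=None,
            bin_edges=np.array([0.0, bin_width]),
            counts=np.array([0]),
        )
    q25, med, q75 = np.percentile(forces, [25, 50, 75], method="linear")
    edges = np.arange(0.0, forces.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(forces, bins=edges)
    return ConditionSummary(
        condition_label=data.condition_label,
        treatment_label=data.treatment_label,
        velocity_v=data.velocity_v,
        n=int(forces.size),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        bin_edges=edges,
        counts=counts,
    )


def velocity_trend(summaries: Sequence[ConditionSummary]) -> VelocitySeries:
    """Least-squares line and Spearman rank correlation of median force
    versus pulling velocity (the pulling-rate series)."""
    pts = sorted((s.velocity_v, s.median) for s in summaries if s.n > 0)
    if len(pts) < 3:
        raise InsufficientDataError(f"velocity trend needs >= 3 velocities, got {len(pts)}")
    v = np.array([p[0] for p in pts])
    m = np.array([p[1] for p in pts])
    fit = sps.linregress(v, m)
    rho = sps.spearmanr(v, m).statistic
    return VelocitySeries(
        velocities=v, medians=m, slope=float(fit.slope), intercept=float(fit.intercept), spearman_rho=float(rho)
    )


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of the permutation null.

    Enumerates every assignment of the pooled (tied-rank) values to group A;
    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))), which gives p = 1 for
    identical samples.
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a].sum(), n_a)
    idx = np.fromiter(
        (i for c in combinations(range(n_a + n_b), n_a) for i in c), dtype=np.intp
    ).reshape(-1, n_a)
    u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
    total = u_all.size
    tol = 1e-9
    p_le = np.count_nonzero(u_all <= u_obs + tol) / total
    p_ge = np.count_nonzero(u_all >= u_obs - tol) / total
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_ranksum(
    a: np.ndarray, b: np.ndarray, label_a: str = "A", label_b: str = "B"
) -> ComparisonResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Small layouts (at most 200k assignments) are evaluated by exact
    enumeration of the permutation null with tied ranks; larger layouts use
    the tie-corrected normal approximation with continuity correction.
    The U statistic reported is for sample ``a`` over ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    if comb(a.size + b.size, min(a.size, b.size)) <= _MAX_EXACT_COMBINATIONS:
        u, p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return ComparisonResult(label_a=label_a, label_b=label_b, u_statistic=u, p_value=p, method=method)


def build_summary_table(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    """Long-format summary table with deterministic row order
    (condition, treatment, velocity)."""
    rows = [
        {
            "condition": s.condition_label,
            "treatment": s.treatment_label,
            "velocity_um_per_s": s.velocity_v,
            "n": s.n,
            "q25_pN": s.q25,
            "median_pN": s.median,
            "q75_pN": s.q75,
        }
        for s in summaries
    ]
    table = pd.DataFrame(rows, columns=["condition", "treatment", "velocity_um_per_s", "n", "q25_pN", "median_pN", "q75_pN"])
    if len(table):
        table = table.sort_values(["condition", "treatment", "velocity_um_per_s"], kind="mergesort").reset_index(
            drop=True
        )
    return table


def compare_treatments(
    control: ConditionDataset, dmso: ConditionDataset, drug: ConditionDataset, drug_label: str = "drug"
) -> dict[tuple[str, str], ComparisonResult]:
    """Pairwise rank-sum comparisons of control, vehicle and drug pools."""
    out = {}
    pairs = [
        (("control", control), ("DMSO", dmso)),
        (("DMSO", dmso), (drug_label, drug)),
        (("control", control), (drug_label, drug)),
    ]
    for (la, da), (lb, db) in pairs:
        out[(la, lb)] = wilcoxon_ranksum(da.rupture_forces, db.rupture_forces, la, lb)
    return out
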