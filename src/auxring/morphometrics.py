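"""Vascular-bundle morphometrics of stem cross sections.

A cross section of the shoot inflorescence stem is reduced to the number
of vascular bundles V, the sizes λ_k of the vascular units (procambial
cells within a bundle plus interfascicular fiber cells up to the next
bundle), and the total provascular-ring cell count N = Σ λ_k, so that
V = N / λ̄ holds by construction.

A change in bundle number between two genotypes is decomposed into a
spacing (λ) contribution and a cell-number (N) contribution.  Writing the
identity V = N/λ in relative changes gives ΔV/V = ΔN/N − Δλ/λ to first
order, so the two fractional effects are f_λ = −Δλ/λ_WT and
f_N = ΔN/N_WT, and each contribution is reported as a percentage of their
sum — the pair always sums to 100%.  Group-level differences per variable
are tested with the Wilcoxon rank-sum test on per-plant averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SectionMeasurement", "GroupComparison", "per_plant_summary",
           "decompose_change", "wilcoxon_rank_sum", "read_sections_csv",
           "EXACT_MAX_N"]

# largest combined sample size handled by exact enumeration
EXACT_MAX_N = 12


@dataclass
class SectionMeasurement:
    """One plant's vascular-ring morphometry."""

    plant_id: str
    unit_sizes: list            # λ_k, cells per vascular unit (positive ints)

    def __post_init__(self) -> None:
        if len(self.unit_sizes) == 0:
            raise ValueError(f"plant {self.plant_id}: no vascular units")
        if any(int(u) != u or u <= 0 for u in self.unit_sizes):
            raise ValueError(f"plant {self.plant_id}: unit sizes must be positive integers")
        self.unit_sizes = [int(u) for u in self.unit_sizes]

    @property
    def V(self) -> int:
        """Vascular-bundle count (one bundle per vascular unit)."""
        return len(self.unit_sizes)

    @property
    def N_ring(self) -> int:
        """Total cell count across the provascular ring."""
        return sum(self.unit_sizes)


@dataclass
class GroupComparison:
    medians_wt: dict            # {"V": .., "lam": .., "N": ..}
    medians_other: dict
    deltas: dict                # other − wt per variable
    f_spacing: float            # −Δλ/λ_WT
    f_cellnumber: float         # ΔN/N_WT
    contribution_spacing_pct: float | None
    contribution_cellnumber_pct: float | None
    undefined: bool             # f_spacing + f_cellnumber == 0
    p_values: dict              # Wilcoxon rank-sum p per variable
    center: str = "median"


def per_plant_summary(section: SectionMeasurement):
    """(V, mean λ, N_ring) for one plant; mean λ = N_ring / V."""
    V = section.V
    N = section.N_ring
    return V, N / V, N


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum test; returns (rank-sum statistic of x, p-value).

    Ties receive midranks.  For combined sample sizes up to 12 the null
    distribution of the rank sum is enumerated exactly over all
    assignments of the observed (mid)ranks; larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    W = float(ranks[:n].sum())
    if n + m <= EXACT_MAX_N:
        total = 0
        hits = 0
        mu = (n + m + 1) * n / 2.0
        obs_dev = abs(W - mu)
        eps = 1e-12
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            total += 1
            if alternative == "two-sided":
                hits += abs(w - mu) >= obs_dev - eps
            elif alternative == "greater":
                hits += w >= W - eps
            else:
                hits += w <= W + eps
        return W, hits / total
    # asymptotic branch: convert through the Mann-Whitney U statistic
    U1 = W - n * (n + 1) / 2.0
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    assert math.isclose(res.statistic, U1), "rank bookkeeping mismatch"
    return W, float(res.pvalue)


def decompose_change(wt, other, center: str = "median"):
    """Spacing-vs-cell-number decomposition of a bundle-number change.

    ``wt`` and ``other`` are sequences of :class:`SectionMeasurement`.
    Group summaries are medians of the per-plant values (means available
    with ``center="mean"``).  The fractional effects implied by V = N/λ,
    f_λ = −Δλ/λ_WT and f_N = ΔN/N_WT, are normalized to percentages of
    their sum, which therefore add up to 100%; when the sum is zero the
    contributions are undefined and flagged.
    """
    if len(wt) == 0 or len(other) == 0:
        raise ValueError("both groups must be non-empty")
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    agg = np.median if center == "median" else np.mean

    def group_stats(sections):
        trip = np.array([per_plant_summary(s) for s in sections], dtype=float)
        return {"V": float(agg(trip[:, 0])), "lam": float(agg(trip[:, 1])),
                "N": float(agg(trip[:, 2]))}, trip

    med_wt, trip_wt = group_stats(wt)
    med_ot, trip_ot = group_stats(other)
    deltas = {k: med_ot[k] - med_wt[k] for k in ("V", "lam", "N")}
    f_lam = -deltas["lam"] / med_wt["lam"]
    f_N = deltas["N"] / med_wt["N"]
    denom = f_lam + f_N
    # a vanishing sum (incl. exact rational cancellation that leaves float
    # dust) means the two effects offset and the split is undefined
    if abs(denom) <= 1e-12 * max(abs(f_lam), abs(f_N), 1e-300):
        c_lam = c_N = None
        undefined = True
    else:
        c_lam = 100.0 * f_lam / denom
        c_N = 100.0 * f_N / denom
        undefined = False
    p_values = {
        "V": wilcoxon_rank_sum(trip_wt[:, 0], trip_ot[:, 0])[1],
        "lam": wilcoxon_rank_sum(trip_wt[:, 1], trip_ot[:, 1])[1],
        "N": wilcoxon_rank_sum(trip_wt[:, 2], trip_ot[:, 2])[1],
    }
    return GroupComparison(
        medians_wt=med_wt, medians_other=med_ot, deltas=deltas,
        f_spacing=f_lam, f_cellnumber=f_N,
        contribution_spacing_pct=c_lam, contribution_cellnumber_pct=c_N,
        undefined=undefined, p_values=p_values, center=center)


def read_sections_csv(path):
    """Read sections from CSV (plant_id, group, unit_size; one row per unit).

    Returns ``{group_name: [SectionMeasurement, ...]}`` with groups and
    plants in order of first appearance.
    """
    df = pd.read_csv(path)
    required = {"plant_id", "group", "unit_size"}
    if not required.issubset(df.columns):
        raise ValueError(f"sections CSV missing columns {sorted(required - set(df.columns))}")
    groups: dict = {}
    for (group, plant), sub in df.groupby(["group", "plant_id"], sort=False):
        groups.setdefault(group, []).append(
            SectionMeasurement(plant_id=str(plant),
                               unit_sizes=sub.unit_size.tolist()))
    return groups
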