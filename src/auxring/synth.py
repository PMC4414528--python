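"""Synthetic inputs with known ground truth.

Two generators back the test pipeline end to end without any external
data: circular auxin-like profiles with a planted number of maxima
(emulating the simulated rings fed to the quantification stage), and
per-plant vascular-ring cohorts with planted group medians (emulating the
wild-type vs influx-mutant cross-section measurements).  Both are pure
functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometrics import SectionMeasurement
from .quantify import INCIPIENT_THRESHOLD

__all__ = ["RingProfileSpec", "CohortSpec", "make_ring_profile", "make_cohort"]


@dataclass(frozen=True)
class RingProfileSpec:
    n_cells: int = 60
    n_maxima_planted: int = 5
    base_level: float = 10.0        # μM
    amplitude: float = 5.0          # μM, half peak-to-trough of the cosine
    noise_sd: float = 0.0           # μM
    incipient_fraction: float = 0.0  # planted shallow extra peaks per main peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maxima_planted < 1 or self.n_maxima_planted > self.n_cells / 2:
            raise ValueError("need 1 <= n_maxima_planted <= n_cells/2")
        if min(self.base_level, self.amplitude, self.noise_sd) < 0:
            raise ValueError("magnitudes must be nonnegative")
        if not 0.0 <= self.incipient_fraction <= 1.0:
            raise ValueError("incipient_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """One group of plants with target medians and integer dispersion."""

    n_plants: int = 24
    median_V: int = 8               # vascular bundles per plant
    median_lambda: int = 10         # cells per vascular unit
    dispersion_V: float = 0.0       # sd of the bundle-count draw
    dispersion_lambda: float = 0.0  # sd of the unit-size draw
    group: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.median_V < 1 or self.median_lambda <= 0:
            raise ValueError("medians must be positive")
        if min(self.dispersion_V, self.dispersion_lambda) < 0:
            raise ValueError("dispersions must be nonnegative")


def make_ring_profile(spec: RingProfileSpec):
    """Circular profile with k planted maxima, optional incipient peaks, noise.

    The backbone is ``base + amplitude·cos(k·θ)`` whose maxima sit at the
    cells nearest θ = 2πm/k.  When ``incipient_fraction > 0``, a matching
    fraction of the troughs receives a single-cell bump small enough that
    its excess over the average minima stays below the 0.15 incipient rule
    by construction.  Gaussian noise (sd ``noise_sd``) is added last and
    the profile is clipped at 0.

    Returns ``(values, true_maxima_idx, incipient_idx)``.
    """
    n, k = spec.n_cells, spec.n_maxima_planted
    theta = 2.0 * np.pi * np.arange(n) / n
    values = spec.base_level + spec.amplitude * np.cos(k * theta)
    true_max = np.unique(np.round(np.arange(k) * n / k).astype(int) % n)
    n_incip = int(round(spec.incipient_fraction * k))
    incipient_idx = []
    if n_incip > 0:
        if n // k < 6:
            raise ValueError("troughs too narrow to plant incipient peaks "
                             "(need n_cells/n_maxima_planted >= 6)")
        # trough centers halfway between consecutive planted maxima
        troughs = (np.round((np.arange(k) + 0.5) * n / k).astype(int) % n)[:n_incip]
        # a bump at a trough must rise above its two cosine neighbors to be
        # detected at all, yet keep (value - avg minima) under 0.15 of the
        # pre-filter amplitude; solve for the midpoint of that window,
        # iterating once since the amplitude depends weakly on the bump
        # highest flanking value over all bump sites (rounding can tilt them)
        v_nb = float(max(max(values[(t + 1) % n], values[(t - 1) % n])
                         for t in troughs))
        v_b = v_nb
        for _ in range(3):
            # minima once bumps are planted: the 2 neighbors of each bump
            # plus the untouched trough bottoms
            minima_vals = ([v_nb] * (2 * n_incip)
                           + [spec.base_level - spec.amplitude] * (k - n_incip))
            avg_min = float(np.mean(minima_vals))
            maxima_vals = [spec.base_level + spec.amplitude] * k + [v_b] * n_incip
            amp_prov = float(np.mean(maxima_vals)) - avg_min
            ceiling = avg_min + INCIPIENT_THRESHOLD * amp_prov
            if ceiling <= v_nb:
                raise ValueError("no room for an incipient peak in this geometry")
            v_b = 0.5 * (v_nb + ceiling)
        values[troughs] = v_b
        incipient_idx = [int(t) for t in troughs]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=n)
    return np.clip(values, 0.0, None), true_max, np.array(sorted(incipient_idx), dtype=int)


def make_cohort(spec: CohortSpec):
    """List of plants whose V and λ_k are discretized draws around the medians.

    Bundle count: V = max(1, round(median_V + N(0, dispersion_V))); unit
    sizes: λ_k = max(2, round(median_λ + N(0, dispersion_λ))) — symmetric
    integer draws whose sample medians converge to the spec medians.  The
    ring total is N = Σ λ_k, so V = N/λ̄ holds for every plant by
    construction.  Zero dispersion reproduces the medians exactly.
    """
    rng = np.random.default_rng(spec.seed)
    plants = []
    for p in range(spec.n_plants):
        V = max(1, int(round(spec.median_V + rng.normal(0.0, spec.dispersion_V))))
        lam = np.maximum(
            2, np.round(spec.median_lambda
                        + rng.normal(0.0, spec.dispersion_lambda, size=V)).astype(int))
        plants.append(SectionMeasurement(
            plant_id=f"{spec.group}-{p:03d}", unit_sizes=lam.tolist()))
    return plants
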