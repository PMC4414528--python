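"""Cell/apoplast auxin-transport dynamics on a periodic ring.

The tissue is a ring of ``n`` cells separated by ``n`` apoplastic
compartments; apoplast ``i`` sits between cell ``i`` and cell ``i+1``
(indices mod ``n``), so the apoplasts adjacent to cell ``i`` are ``i-1``
and ``i``.  Cytosolic auxin ``A_i`` and apoplastic auxin ``a_j`` evolve
under

* polar active efflux (PIN-type carriers, polarized toward the neighbor
  with more cytosolic auxin),
* homogeneous active influx (AUX1/LAX-type carriers),
* passive chemiosmotic entry of the protonated fraction (inward only),
* apoplast-to-apoplast diffusion, and
* production and first-order degradation inside cells.

All fluxes are linear in the transported concentration; carrier totals
saturate with cytosolic auxin (Hill coefficient 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RingGeometry",
    "RingState",
    "TransportParams",
    "CarrierDistribution",
    "NumericsError",
    "carrier_totals",
    "efflux_polarization",
    "membrane_fluxes",
    "rhs",
    "homogeneous_steady_state",
    "load_params",
    "dump_params",
    "write_state_csv",
    "read_state_csv",
]


class NumericsError(RuntimeError):
    """Raised when a state contains NaN/Inf or an integration diverges."""


@dataclass(frozen=True)
class RingGeometry:
    """Ring of ``n_cells`` cells and as many apoplastic compartments.

    Apoplast ``i`` lies between cell ``i`` and cell ``i+1`` (mod n), so
    cell ``i`` exchanges auxin with apoplasts ``i-1`` (left) and ``i``
    (right).
    """

    n_cells: int

    def __post_init__(self) -> None:
        if int(self.n_cells) != self.n_cells or self.n_cells < 3:
            raise ValueError(f"n_cells must be an integer >= 3, got {self.n_cells!r}")


@dataclass
class RingState:
    """Paired cytosolic (A) and apoplastic (a) auxin concentrations, in μM."""

    A: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.A.ndim != 1 or self.A.shape != self.a.shape:
            raise ValueError("A and a must be 1-d vectors of equal length")
        if len(self.A) < 3:
            raise ValueError("ring needs at least 3 cells")
        if np.any(self.A < 0) or np.any(self.a < 0):
            raise ValueError("auxin concentrations must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.A)

    def copy(self) -> "RingState":
        return RingState(self.A.copy(), self.a.copy())


# Default parameter set: the wild-type working point of the transport model
# (E = 105 μM/s, D = 2 /s, D_ca = 15 /s, θ_I = θ_P = 10 μM, I = 100 μM/s).
# σ_c/ν_c fixes the homogeneous cytosolic level at A* = 10 μM, the carrier
# half-saturation point, so carrier induction is fully active; turnover is
# slow relative to transport (ν_c = 0.1) and the apoplast is thin relative
# to the cell (ρ = 10), which places the whole D = 2 influx sweep inside
# the patterning region as in the reference phase diagram.
@dataclass(frozen=True)
class TransportParams:
    I: float = 100.0        # active influx intensity (μM s⁻¹)
    E: float = 105.0        # active efflux intensity (μM s⁻¹)
    D: float = 2.0          # apoplast-apoplast diffusion rate (s⁻¹)
    D_ca: float = 15.0      # passive (protonated) influx rate (s⁻¹)
    sigma_c: float = 1.0    # auxin production inside cells (μM per unit time)
    nu_c: float = 0.1       # auxin degradation inside cells (per unit time)
    theta_I: float = 10.0   # influx-carrier synthesis half-saturation (μM)
    theta_P: float = 10.0   # efflux-carrier synthesis half-saturation (μM)
    rho: float = 10.0       # V_cell / V_apoplast volume ratio
    w: float = 1.0          # membrane area-to-volume factor (effective rate)
    a_ref: float = 1.0      # reference apoplastic concentration (μM)
    A_ref: float = 1.0      # reference cytosolic concentration (μM)
    polarity_exponent: float = 1.0  # exponent of the efflux-polarity weighting
    time_scale: float = 1.0  # dimensional-to-nondimensional time factor

    def __post_init__(self) -> None:
        for name in ("I", "E", "D", "D_ca", "sigma_c", "nu_c",
                     "theta_I", "theta_P", "w", "polarity_exponent", "time_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("rho", "a_ref", "A_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def with_(self, **kwargs) -> "TransportParams":
        return replace(self, **kwargs)


@dataclass
class CarrierDistribution:
    """Per-cell carrier totals and the left/right split of efflux carriers.

    ``i_tot`` ≤ 1/2 and ``p_tot`` ≤ 1 are the normalized totals of influx
    and efflux carriers; ``phi_left``/``phi_right`` are the fractions of
    efflux carriers facing apoplast i-1 and apoplast i (they sum to 1).
    """

    i_tot: np.ndarray
    p_tot: np.ndarray
    phi_left: np.ndarray
    phi_right: np.ndarray


def _check_nonnegative(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("cytosolic auxin must be nonnegative")
    return A


def carrier_totals(A, params: TransportParams):
    """Saturating carrier totals I_T(A) = (1/2)·A/(θ_I+A), P_T(A) = A/(θ_P+A).

    With θ_I = θ_P = 0 the totals are constant at (1/2, 1) for every cell
    (carrier synthesis independent of auxin), by convention also at A = 0.
    """
    A = _check_nonnegative(A)
    if params.theta_I == 0.0:
        i_tot = np.full_like(A, 0.5)
    else:
        i_tot = 0.5 * A / (params.theta_I + A)
    if params.theta_P == 0.0:
        p_tot = np.ones_like(A)
    else:
        p_tot = A / (params.theta_P + A)
    return i_tot, p_tot


def efflux_polarization(A, geometry: RingGeometry | None = None,
                        polarity_exponent: float = 1.0):
    """Equilibrium left/right split of efflux carriers in each cell.

    The fraction of cell i's efflux carriers facing apoplast i (toward
    cell i+1) is A_{i+1}^n / (A_{i+1}^n + A_{i-1}^n); the remainder faces
    apoplast i-1.  When both neighbor weights vanish the split is 1/2–1/2,
    which keeps the dynamics continuous at the origin.
    """
    A = _check_nonnegative(A)
    n = polarity_exponent
    with np.errstate(over="ignore"):
        w_right = np.roll(A, -1) ** n
        w_left = np.roll(A, 1) ** n
        tot = w_right + w_left
    ok = np.isfinite(tot) & (tot > 0)
    phi_right = np.where(ok, np.divide(w_right, tot, where=ok, out=np.full_like(tot, 0.5)), 0.5)
    # overflowed weights: fall back to a 0/1 comparison of the neighbors
    bad = ~np.isfinite(tot)
    if np.any(bad):
        right_gt = np.roll(A, -1) > np.roll(A, 1)
        left_gt = np.roll(A, 1) > np.roll(A, -1)
        phi_right = np.where(bad, np.where(right_gt, 1.0, np.where(left_gt, 0.0, 0.5)), phi_right)
    return 1.0 - phi_right, phi_right


def membrane_fluxes(state: RingState, params: TransportParams,
                    carriers: CarrierDistribution | None = None):
    """Net flux cell → apoplast on each membrane, (J_left, J_right) per cell.

    ``J_right[i]`` crosses the membrane between cell i and apoplast i,
    ``J_left[i]`` the one between cell i and apoplast i-1::

        J = E·P_T(A_i)·φ·A_i/A_ref − I·I_T(A_i)·a/a_ref − D_ca·a

    Efflux acts only outward; active influx and passive entry only inward
    (chemiosmotic trapping: the anionic form cannot leave passively).
    """
    A, a = state.A, state.a
    if carriers is None:
        i_tot, p_tot = carrier_totals(A, params)
        phi_left, phi_right = efflux_polarization(A, None, params.polarity_exponent)
    else:
        i_tot, p_tot = carriers.i_tot, carriers.p_tot
        phi_left, phi_right = carriers.phi_left, carriers.phi_right
        if len(i_tot) != len(A):
            raise ValueError("carrier vectors do not match state length")
    efflux = params.E * p_tot * A / params.A_ref
    uptake = params.I * i_tot / params.a_ref + params.D_ca
    a_left = np.roll(a, 1)  # apoplast i-1 seen from cell i
    J_right = efflux * phi_right - uptake * a
    J_left = efflux * phi_left - uptake * a_left
    return J_left, J_right


def rhs(state: RingState, params: TransportParams):
    """Time derivatives (dA, da) of the ring dynamics.

    dA_i = −w·(J_left,i + J_right,i) − ν_c·A_i + σ_c
    da_j = +w·ρ·(J_right,j + J_left,j+1) + D·(a_{j-1} − 2a_j + a_{j+1})

    both multiplied by ``time_scale`` so reported time is nondimensional.
    With σ_c = ν_c = 0 transport conserves Σ A + (1/ρ)·Σ a exactly.
    """
    if not (np.all(np.isfinite(state.A)) and np.all(np.isfinite(state.a))):
        raise NumericsError("non-finite auxin concentration in state")
    J_left, J_right = membrane_fluxes(state, params)
    a = state.a
    dA = -params.w * (J_left + J_right) - params.nu_c * state.A + params.sigma_c
    da = (params.w * params.rho * (J_right + np.roll(J_left, -1))
          + params.D * (np.roll(a, 1) - 2.0 * a + np.roll(a, -1)))
    ts = params.time_scale
    return ts * dA, ts * da


def homogeneous_steady_state(params: TransportParams):
    """Spatially uniform fixed point (A*, a*) of the ring dynamics.

    At a uniform state diffusion vanishes and the net flux across every
    membrane must vanish, so production balances degradation: A* = σ_c/ν_c.
    Each cell drains through its two membranes with the efflux split half
    and half, so the apoplastic level solves the per-membrane balance
    (1/2)·E·P_T(A*)·A*/A_ref = (I·I_T(A*)/a_ref + D_ca)·a*.
    """
    if params.nu_c <= 0:
        raise ValueError("nu_c must be positive for a homogeneous steady state")
    A_star = params.sigma_c / params.nu_c
    i_tot, p_tot = carrier_totals(np.array([A_star]), params)
    efflux = params.E * p_tot[0] * A_star / params.A_ref
    uptake = params.I * i_tot[0] / params.a_ref + params.D_ca
    if efflux == 0.0:
        a_star = 0.0
    elif uptake == 0.0:
        raise ValueError("no finite apoplastic steady state: efflux with zero uptake")
    else:
        a_star = 0.5 * efflux / uptake
    return A_star, a_star


# ---------------------------------------------------------------------------
# parameter and state I/O

_PARAM_NAMES = tuple(f.name for f in dc_fields(TransportParams))


def load_params(path) -> TransportParams:
    """Read a TransportParams from a YAML (or JSON) key-value file.

    Unknown keys are rejected by name; missing keys fall back to the
    defaults above.  An empty file yields the full default set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    unknown = sorted(set(data) - set(_PARAM_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    for key, val in data.items():
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ValueError(f"parameter {key} must be a number, got {val!r}")
    return TransportParams(**{k: float(v) for k, v in data.items()})


def dump_params(params: TransportParams, path) -> None:
    data = {name: getattr(params, name) for name in _PARAM_NAMES}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_state_csv(state: RingState, path, time: float = 0.0) -> None:
    """Write a snapshot as tidy CSV: compartment_type, index, concentration_uM, time."""
    n = state.n_cells
    df = pd.DataFrame({
        "compartment_type": ["cyto"] * n + ["apo"] * n,
        "index": list(range(n)) * 2,
        "concentration_uM": np.concatenate([state.A, state.a]),
        "time": time,
    })
    df.to_csv(path, index=False)


def read_state_csv(path) -> RingState:
    df = pd.read_csv(path)
    required = {"compartment_type", "index", "concentration_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"state CSV missing columns {sorted(required - set(df.columns))}")
    cyto = df[df.compartment_type == "cyto"].sort_values("index")
    apo = df[df.compartment_type == "apo"].sort_values("index")
    return RingState(cyto.concentration_uM.to_numpy(), apo.concentration_uM.to_numpy())
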