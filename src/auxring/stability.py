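"""Linear stability analysis of the homogeneous state on the ring.

The uniform fixed point (A*, a*) is linearized analytically.  Because the
dynamics commute with ring rotation, the 2N×2N Jacobian is block-circulant
and its spectrum decomposes into 2×2 blocks, one per integer Fourier mode
q = 0 … ⌊N/2⌋ with phase ω = 2πq/N.  The homogeneous state is classified
patterning (P) when some mode q ≥ 1 has a positive growth rate; the
fastest-growing mode q* predicts the characteristic wavenumber
κ = q*/N (auxin maxima per cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TransportParams, carrier_totals, homogeneous_steady_state

__all__ = ["StabilityReport", "linearization_coefficients", "jacobian",
           "dispersion", "phase_diagram"]


@dataclass
class StabilityReport:
    params: TransportParams
    n_cells: int
    growth_rates: np.ndarray      # leading real part per mode q = 0..N//2
    fastest_mode: int             # argmax over q >= 1 (ties -> smaller q)
    kappa_theory: float           # fastest_mode / n_cells
    is_patterning: bool           # max growth over q >= 1 is > 0
    A_star: float
    a_star: float


def _carrier_derivatives(A_star: float, params: TransportParams):
    """(I_T, I_T', P_T, P_T') at the homogeneous cytosolic level."""
    i_tot, p_tot = carrier_totals(np.array([A_star]), params)
    if params.theta_I == 0.0:
        d_i = 0.0
    else:
        d_i = 0.5 * params.theta_I / (params.theta_I + A_star) ** 2
    if params.theta_P == 0.0:
        d_p = 0.0
    else:
        d_p = params.theta_P / (params.theta_P + A_star) ** 2
    return i_tot[0], d_i, p_tot[0], d_p


def linearization_coefficients(params: TransportParams):
    """Scalar coefficients of the linearized dynamics about (A*, a*).

    Returns a dict with:
      g   : total efflux E·P_T(A*)·A*/A_ref at the fixed point
      gp  : d/dA of the total efflux
      h   : per-membrane uptake coefficient I·I_T(A*)/a_ref + D_ca
      hp  : d/dA of the uptake coefficient
      c   : derivative of the polarity fraction w.r.t. a neighbor, n/(4A*)
    """
    A_star, a_star = homogeneous_steady_state(params)
    i_tot, d_i, p_tot, d_p = _carrier_derivatives(A_star, params)
    g = params.E * p_tot * A_star / params.A_ref
    gp = params.E * (d_p * A_star + p_tot) / params.A_ref
    h = params.I * i_tot / params.a_ref + params.D_ca
    hp = params.I * d_i / params.a_ref
    # polarity fractions are 1/2 at a uniform state; their derivative with
    # respect to a single neighbor concentration is n/(4A*).  At A* = 0 the
    # tie rule makes the split constant, so the derivative is taken as 0.
    c = params.polarity_exponent / (4.0 * A_star) if A_star > 0 else 0.0
    return {"A_star": A_star, "a_star": a_star, "g": g, "gp": gp,
            "h": h, "hp": hp, "c": c}


def jacobian(params: TransportParams, n_cells: int) -> np.ndarray:
    """Analytic 2N×2N Jacobian of the dynamics at the homogeneous state.

    Row/column order: N cytosolic entries then N apoplastic entries.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    co = linearization_coefficients(params)
    a_star, g, gp, h, hp, c = (co["a_star"], co["g"], co["gp"],
                               co["h"], co["hp"], co["c"])
    w, rho, nu, ts = params.w, params.rho, params.nu_c, params.time_scale
    N = n_cells
    J = np.zeros((2 * N, 2 * N))
    for i in range(N):
        # cytosol row: dA_i = -w(g(A_i) - h(A_i)(a_{i-1}+a_i)) - nu A_i + sigma
        J[i, i] = ts * (-w * gp + 2.0 * w * hp * a_star - nu)
        J[i, N + (i - 1) % N] += ts * w * h
        J[i, N + i] += ts * w * h
        # apoplast row j = i
        j = i
        r = N + j
        J[r, (j - 1) % N] += ts * w * rho * (-g * c)
        J[r, j % N] += ts * w * rho * (0.5 * gp + g * c - hp * a_star)
        J[r, (j + 1) % N] += ts * w * rho * (0.5 * gp + g * c - hp * a_star)
        J[r, (j + 2) % N] += ts * w * rho * (-g * c)
        J[r, N + j] += ts * (-2.0 * w * rho * h - 2.0 * params.D)
        J[r, N + (j - 1) % N] += ts * params.D
        J[r, N + (j + 1) % N] += ts * params.D
    return J


def _mode_block(params: TransportParams, co: dict, omega: float) -> np.ndarray:
    """2×2 Fourier block of the block-circulant Jacobian at phase ω."""
    a_star, g, gp, h, hp, c = (co["a_star"], co["g"], co["gp"],
                               co["h"], co["hp"], co["c"])
    w, rho, nu, ts = params.w, params.rho, params.nu_c, params.time_scale
    z = np.exp(1j * omega)
    m11 = ts * (-w * gp + 2.0 * w * hp * a_star - nu)
    m12 = ts * w * h * (1.0 + 1.0 / z)
    m21 = ts * w * rho * ((0.5 * gp + g * c - hp * a_star) * (1.0 + z)
                          - g * c * (1.0 / z + z * z))
    m22 = ts * (-2.0 * w * rho * h - 2.0 * params.D * (1.0 - np.cos(omega)))
    return np.array([[m11, m12], [m21, m22]], dtype=complex)


def growth_rate(params: TransportParams, n_cells: int, q: int,
                co: dict | None = None) -> float:
    """Leading real part of the 2×2 block spectrum for Fourier mode q."""
    if co is None:
        co = linearization_coefficients(params)
    omega = 2.0 * np.pi * q / n_cells
    eig = np.linalg.eigvals(_mode_block(params, co, omega))
    return float(np.max(eig.real))


def dispersion(params: TransportParams, n_cells: int) -> StabilityReport:
    """Growth rate of every Fourier mode and the predicted wavenumber κ.

    Ties for the fastest mode are broken toward the smaller q (the longer
    wavelength).
    """
    co = linearization_coefficients(params)
    n_modes = n_cells // 2 + 1
    rates = np.empty(n_modes)
    for q in range(n_modes):
        rates[q] = growth_rate(params, n_cells, q, co)
    # argmax over q >= 1; exact ties go to the smaller q via argmax order
    q_star = 1 + int(np.argmax(rates[1:]))
    is_patterning = bool(rates[q_star] > 0.0)
    return StabilityReport(
        params=params, n_cells=n_cells, growth_rates=rates,
        fastest_mode=q_star, kappa_theory=q_star / n_cells,
        is_patterning=is_patterning,
        A_star=co["A_star"], a_star=co["a_star"],
    )


def phase_diagram(params: TransportParams, n_cells: int, axis1: str,
                  values1, axis2: str, values2) -> list[StabilityReport]:
    """Dispersion analysis over a 2-d grid of two parameter axes.

    ``axis1``/``axis2`` name TransportParams fields (e.g. "I" and "D" or
    "I" and "E"); all other parameters stay fixed.  Returns the reports in
    row-major order (axis1 outer, axis2 inner).
    """
    reports = []
    for v1 in values1:
        for v2 in values2:
            p = params.with_(**{axis1: float(v1), axis2: float(v2)})
            reports.append(dispersion(p, n_cells))
    return reports
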