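"""Fixed-step RK4 integration and replicate ensembles.

Simulations start from the homogeneous steady state perturbed by small
multiplicative uniform noise and are integrated with a classical 4-stage
Runge-Kutta scheme at a fixed step (default dt = 1e-4 up to t = 17.5,
nondimensional time).  Ensembles of replicates differ only in the seed of
the initial perturbation (seed = base_seed + replicate index), mirroring
the 30-replicate protocol used for the boxplot statistics.

The inner loop is compiled with numba; the jitted right-hand side is a
transcription of :func:`auxring.model.rhs` and a unit test pins their
agreement to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import NumericsError, RingState, TransportParams, homogeneous_steady_state
from .quantify import PatternSummary, summarize

__all__ = ["SimulationConfig", "EnsembleResult", "initial_state",
           "integrate_rk4", "run_ensemble"]


@dataclass
class SimulationConfig:
    params: TransportParams = field(default_factory=TransportParams)
    n_cells: int = 60
    dt: float = 1e-4
    t_end: float = 17.5
    noise_amplitude: float = 0.01
    n_replicates: int = 30
    base_seed: int = 0
    snapshot_times: tuple = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")


@dataclass
class EnsembleResult:
    config: SimulationConfig
    final_states: list          # RingState per replicate
    summaries: list             # (PatternSummary cyto, PatternSummary apo) per replicate
    seeds: list                 # seed ledger, one entry per replicate
    snapshots: list             # per replicate: list of (t, RingState)
    failures: list              # (replicate, message) for aborted integrations


def initial_state(params: TransportParams, n_cells: int,
                  noise_amplitude: float, seed: int) -> RingState:
    """Homogeneous steady state with multiplicative uniform noise.

    A_i = A*(1 + ε u_i), a_j = a*(1 + ε v_j), u, v ~ U(−1, 1) i.i.d.;
    entries are clipped at zero (only reachable when ε ≥ 1).
    """
    A_star, a_star = homogeneous_steady_state(params)
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=n_cells)
    v = rng.uniform(-1.0, 1.0, size=n_cells)
    A = np.clip(A_star * (1.0 + noise_amplitude * u), 0.0, None)
    a = np.clip(a_star * (1.0 + noise_amplitude * v), 0.0, None)
    return RingState(A, a)


@njit(cache=True)
def _rhs_kernel(A, a, dA, da, I, E, D, D_ca, sigma_c, nu_c, theta_I, theta_P,
                rho, w, a_ref, A_ref, pol_n, ts):  # pragma: no cover - jitted
    n = A.shape[0]
    for i in range(n):
        Ai = A[i]
        if theta_I == 0.0:
            i_tot = 0.5
        else:
            i_tot = 0.5 * Ai / (theta_I + Ai)
        if theta_P == 0.0:
            p_tot = 1.0
        else:
            p_tot = Ai / (theta_P + Ai)
        wr = A[(i + 1) % n] ** pol_n
        wl = A[(i - 1) % n] ** pol_n
        tot = wr + wl
        phi_r = wr / tot if tot > 0.0 else 0.5
        phi_l = 1.0 - phi_r
        efflux = E * p_tot * Ai / A_ref
        uptake = I * i_tot / a_ref + D_ca
        J_right = efflux * phi_r - uptake * a[i]
        J_left = efflux * phi_l - uptake * a[(i - 1) % n]
        dA[i] = ts * (-w * (J_left + J_right) - nu_c * Ai + sigma_c)
        # deposit flux contributions into the two adjacent apoplasts
        da[i] += ts * w * rho * J_right
        da[(i - 1) % n] += ts * w * rho * J_left
    for j in range(n):
        da[j] += ts * D * (a[(j - 1) % n] - 2.0 * a[j] + a[(j + 1) % n])


@njit(cache=True)
def _rk4_kernel(A, a, dt, n_steps, p):  # pragma: no cover - jitted
    """In-place classical RK4; p packs the 14 TransportParams scalars.

    Returns the first step index at which the state went non-finite, or -1.
    """
    n = A.shape[0]
    kA1 = np.zeros(n); ka1 = np.zeros(n)
    kA2 = np.zeros(n); ka2 = np.zeros(n)
    kA3 = np.zeros(n); ka3 = np.zeros(n)
    kA4 = np.zeros(n); ka4 = np.zeros(n)
    for step in range(n_steps):
        kA1[:] = 0.0; ka1[:] = 0.0
        _rhs_kernel(A, a, kA1, ka1, p[0], p[1], p[2], p[3], p[4], p[5], p[6],
                    p[7], p[8], p[9], p[10], p[11], p[12], p[13])
        kA2[:] = 0.0; ka2[:] = 0.0
        _rhs_kernel(A + 0.5 * dt * kA1, a + 0.5 * dt * ka1, kA2, ka2,
                    p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8],
                    p[9], p[10], p[11], p[12], p[13])
        kA3[:] = 0.0; ka3[:] = 0.0
        _rhs_kernel(A + 0.5 * dt * kA2, a + 0.5 * dt * ka2, kA3, ka3,
                    p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8],
                    p[9], p[10], p[11], p[12], p[13])
        kA4[:] = 0.0; ka4[:] = 0.0
        _rhs_kernel(A + dt * kA3, a + dt * ka3, kA4, ka4,
                    p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8],
                    p[9], p[10], p[11], p[12], p[13])
        for i in range(n):
            A[i] += dt / 6.0 * (kA1[i] + 2.0 * kA2[i] + 2.0 * kA3[i] + kA4[i])
            a[i] += dt / 6.0 * (ka1[i] + 2.0 * ka2[i] + 2.0 * ka3[i] + ka4[i])
        ok = True
        for i in range(n):
            if not (np.isfinite(A[i]) and np.isfinite(a[i])):
                ok = False
        if not ok:
            return step
    return -1


def _pack(params: TransportParams) -> np.ndarray:
    return np.array([params.I, params.E, params.D, params.D_ca, params.sigma_c,
                     params.nu_c, params.theta_I, params.theta_P, params.rho,
                     params.w, params.a_ref, params.A_ref,
                     params.polarity_exponent, params.time_scale])


def rhs_compiled(state: RingState, params: TransportParams):
    """Jitted right-hand side; must agree with :func:`auxring.model.rhs`."""
    dA = np.zeros(state.n_cells)
    da = np.zeros(state.n_cells)
    p = _pack(params)
    _rhs_kernel(state.A, state.a, dA, da, p[0], p[1], p[2], p[3], p[4], p[5],
                p[6], p[7], p[8], p[9], p[10], p[11], p[12], p[13])
    return dA, da


def integrate_rk4(state: RingState, params: TransportParams, dt: float,
                  t_end: float, snapshot_times=()):
    """Integrate with classical RK4 at fixed step dt up to t_end.

    Returns ``(final_state, snapshots)`` where snapshots is a list of
    ``(t, RingState)`` at the requested times (each matched to the nearest
    step boundary, which must lie within dt/2).  Divergence aborts with
    the offending time and the largest state magnitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_total = int(round(t_end / dt))
    snap_steps = []
    for t_req in snapshot_times:
        s = int(round(t_req / dt))
        if abs(s * dt - t_req) > 0.5 * dt or s < 0 or s > n_total:
            raise ValueError(f"snapshot time {t_req} does not sit on the dt grid")
        snap_steps.append(s)
    A = state.A.copy()
    a = state.a.copy()
    p = _pack(params)
    snapshots = []
    done = 0
    for s in sorted(set(snap_steps)):
        bad = _rk4_kernel(A, a, dt, s - done, p)
        if bad >= 0:
            t_bad = (done + bad) * dt
            raise NumericsError(
                f"integration diverged at t≈{t_bad:.4g}; "
                f"max |state| = {np.nanmax(np.abs(np.concatenate([A, a]))):.3g}")
        done = s
        snapshots.append((s * dt, RingState(np.clip(A, 0, None), np.clip(a, 0, None))))
    bad = _rk4_kernel(A, a, dt, n_total - done, p)
    if bad >= 0:
        t_bad = (done + bad) * dt
        raise NumericsError(
            f"integration diverged at t≈{t_bad:.4g}; "
            f"max |state| = {np.nanmax(np.abs(np.concatenate([A, a]))):.3g}")
    low = min(A.min(), a.min())
    if low < -1e-9:
        raise NumericsError(f"integration produced negative concentration {low:.3g}")
    final = RingState(np.clip(A, 0, None), np.clip(a, 0, None))
    return final, snapshots


def run_ensemble(config: SimulationConfig) -> EnsembleResult:
    """Integrate ``n_replicates`` initial conditions and summarize each.

    Replicate r draws its initial noise from seed ``base_seed + r``; a
    diverging replicate is recorded in ``failures`` rather than dropped
    silently.
    """
    finals, summaries, seeds, snaps, failures = [], [], [], [], []
    for r in range(config.n_replicates):
        seed = config.base_seed + r
        seeds.append(seed)
        state0 = initial_state(config.params, config.n_cells,
                               config.noise_amplitude, seed)
        try:
            final, snapshots = integrate_rk4(state0, config.params, config.dt,
                                             config.t_end, config.snapshot_times)
        except NumericsError as err:
            failures.append((r, str(err)))
            finals.append(None)
            summaries.append(None)
            snaps.append([])
            continue
        finals.append(final)
        summaries.append(summarize(final))
        snaps.append(snapshots)
    return EnsembleResult(config=config, final_states=finals,
                          summaries=summaries, seeds=seeds,
                          snapshots=snaps, failures=failures)
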