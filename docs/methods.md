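# Methods

## The transport model

The tissue is an idealized provascular ring: `N` cells, each separated
from its neighbors by an apoplastic compartment, so apoplast `i` sits
between cell `i` and cell `i+1` (indices mod `N`). Two concentration
fields evolve: cytosolic auxin `A_i` and apoplastic auxin `a_i`, both in
μM. Auxin inside a cell is taken as well mixed (cytosolic diffusion is
fast relative to transport), and the ring neither grows nor divides.

Per membrane between cell `i` and adjacent apoplast `j ∈ {i−1, i}`, the
net outward flux is linear in the transported concentration:

    J(i→j) = E·P_T(A_i)·φ_ij·(A_i/A_ref) − I·I_T(A_i)·(a_j/a_ref) − D_ca·a_j

with the three terms being polar active efflux (PIN-type carriers),
homogeneous active influx (AUX1/LAX-type carriers) and passive entry of
the protonated fraction. Both active influx and passive entry act only
inward: the chemiosmotic mechanism traps the deprotonated anion inside
the cell, so there is no passive efflux term. The field equations are

    dA_i/dτ = −w·Σ_j J(i→j) − ν_c·A_i + σ_c
    da_j/dτ = +w·ρ·Σ_i J(i→j) + D·(a_{j−1} − 2a_j + a_{j+1})

where `w` folds the membrane area-to-volume ratio into an effective rate,
`ρ = V_cell/V_ap` converts cell-volume fluxes to apoplast concentrations,
`D` is the effective apoplast-to-apoplast diffusion rate, and σ_c, ν_c
are production and first-order degradation inside cells. With
σ_c = ν_c = 0 the dynamics conserve `Σ A + (1/ρ)·Σ a` exactly; this is
used as an integration check.

Carrier totals saturate with cytosolic auxin,

    I_T(A) = (1/2)·A/(θ_I + A),   P_T(A) = A/(θ_P + A),

normalized to 1/2 (influx) and 1 (efflux); θ_I = θ_P = 0 switches to the
constant-carrier variant (totals pinned at 1/2 and 1, by convention also
at A = 0). Efflux carriers polarize toward the neighbor with more
cytosolic auxin, at equilibrium: the fraction of cell `i`'s efflux
carriers facing apoplast `i` is

    φ_i = A_{i+1}^n / (A_{i+1}^n + A_{i−1}^n),

with exponent `n = 1` by default. When both neighbor weights vanish the
split is 1/2–1/2, which keeps the right-hand side continuous at the
origin.

### Units and reference concentrations

`I` and `E` are quoted in μM s⁻¹ while the fluxes are linear in the
transported concentration; the two conventions are reconciled by fixed
reference concentrations `A_ref = a_ref = 1 μM` dividing the transported
concentration, which preserves the printed parameter values. Time is
reported nondimensionally; `time_scale` (default 1) converts the
dimensional rates, i.e. all quoted rates are treated as effective rates
per nondimensional time unit.

### Homogeneous steady state

At a uniform state diffusion vanishes and each membrane must carry zero
net flux, forcing production–degradation balance in the cell and a
per-membrane flux balance with the efflux split half per side:

    A* = σ_c/ν_c,
    (1/2)·E·P_T(A*)·A*/A_ref = [I·I_T(A*)/a_ref + D_ca]·a*.

The returned pair satisfies `‖rhs‖∞ < 1e−10`, and a unit test pins it
against an independent damped-Newton root solve of the uniform dynamics.
Note the factor 1/2: each cell drains through two membranes, so omitting
it overestimates `a*` by exactly a factor of two and the resulting pair
is *not* a fixed point of the dynamics.

## Default parameters

| name | default | meaning |
|---|---|---|
| I | 100 μM s⁻¹ | active influx intensity (swept 10⁻³…10³) |
| E | 105 μM s⁻¹ | active efflux intensity |
| D | 2 s⁻¹ | apoplastic diffusion rate |
| D_ca | 15 s⁻¹ | passive influx rate (50 in the efflux-sweep analyses) |
| θ_I = θ_P | 10 μM | carrier-synthesis half-saturation (0 = constant carriers) |
| σ_c | 1 μM/t | production inside cells |
| ν_c | 0.1 /t | degradation inside cells |
| ρ | 10 | cell-to-apoplast volume ratio |
| w | 1 | membrane area-to-volume factor |
| a_ref, A_ref | 1 μM | reference concentrations of the linear fluxes |
| n (polarity) | 1 | exponent of the efflux-polarization weighting |

E, D, D_ca and θ are the published working point. σ_c, ν_c, ρ and w are
not published as effective nondimensional values and were calibrated
once, from the linear stability structure alone, to the qualitative
facts the reference analyses state: σ_c/ν_c = 10 μM places the uniform
cytosolic level exactly at the carrier half-saturation point (carrier
induction active, A* = θ); ν_c = 0.1 makes turnover slow relative to
transport, as it is physically (auxin half-life of minutes to hours vs
transport timescales of seconds); ρ = 10 reflects a thin apoplast
relative to the cell volume. With these values the model reproduces the
expected phase structure: the whole influx sweep at D = 2 s⁻¹ lies in
the patterning region with κ rising from 0.117 to 0.15; patterning at
D = 50 s⁻¹ requires high influx; the efflux threshold is approached from
below (no patterning without polar efflux, at any influx); and κ on 60
and 1200 cells agree within one mode spacing. These defaults were not
revisited afterwards. With ρ = w = ν_c = 1 the low-influx end of the
D = 2 sweep is linearly stable instead — the instability is real but the
unpublished effective geometry factors control where the boundary sits.

## Linear stability analysis

The right-hand side is linearized analytically about (A*, a*); the
derivative of the polarization fraction with respect to a neighbor
concentration at the uniform state is `n/(4A*)` (taken as 0 at A* = 0,
where the tie rule makes the split constant). Rotation symmetry makes
the 2N×2N Jacobian block-circulant, so its spectrum splits into 2×2
Fourier blocks at phases ω = 2πq/N, q = 0…⌊N/2⌋. The growth rate of
mode q is the largest real part of its block eigenvalues; the state is
classified patterning (P) when some q ≥ 1 grows, and the predicted
wavenumber is κ = q*/N with q* the fastest mode. Exact ties are broken
toward the smaller q (the longer wavelength) — deterministic and
conservative. κ is reported on the integer mode grid of the finite
ring, not as a continuous-wavenumber optimum. The analytic Jacobian is
cross-checked entrywise against central finite differences
(step 1e−6·max(A*, 1), relative tolerance 1e−5) and the block spectra
against full-matrix eigensolves (1e−8), over random parameter draws.

## Simulation protocol

Classical fixed-step RK4 (no adaptivity) with dt = 1e−4 up to
t_end = 17.5, N = 60 cells. The stiffest linear rate at the wild-type
point is ≈ 800 per time unit (apoplast drainage), well inside the RK4
stability region at this step (|λ|dt ≈ 0.08); dt ≳ 3.5e−3 diverges.
Initial conditions are the homogeneous state under multiplicative
uniform noise, `A_i = A*(1 + ε u_i)` with `u_i ~ U(−1,1)` and ε = 0.01
(the reference protocol says only "small variability"; a scale-free
relative perturbation was chosen). Ensembles run 30 replicates with
seeds `base_seed + replicate`; reproducibility is bitwise for a fixed
config. Self-convergence of the integrator is fourth order (log–log
slope 4 ± 0.3 against dt/16 references) and transport conserves total
auxin to < 1e−8 relative over the full horizon.

## Pattern quantification

Extrema are strict local maxima/minima under periodic wrap; a flat
plateau strictly above (below) both flanking runs counts once, at its
lowest member index (strictness avoids double-counting; the discrete
extremum rule is otherwise unconstrained by the source protocol). A
maximum is *incipient* when its excess over the average minima is below
0.15 of the pattern amplitude. The amplitude used inside the filter is
the pre-filter amplitude `avg(all maxima) − avg(all minima)`, computed
once (no iteration); reported statistics (κ = retained maxima/N,
amplitude, average maxima/minima, ring mean) are then recomputed on the
retained maxima. Minima are never filtered. The filter is ratio-based,
so all statistics are rotation-invariant and scale-covariant; both
properties are tested exactly, and the detector is pinned to a
brute-force neighbor-walk oracle on every ring of length ≤ 8 over a
three-letter alphabet.

## Vascular morphometrics

Each plant contributes a vascular-unit size list λ_k; V is the unit
count and N = Σλ_k the ring total, so V = N/λ̄ holds per plant by
construction. Group summaries are medians (means optional). The bundle
number change decomposes through V = N/λ into fractional effects
f_λ = −Δλ/λ_WT and f_N = ΔN/N_WT, reported as percentages of their sum
(always summing to 100%); the printed relation with both signs positive
is inconsistent with V = N/λ, and the sign forced by the identity is
used. The raw fractional effects are also emitted. Note the percentages
are *not* exactly invariant to swapping which group is the reference —
the normalization is by the reference baseline — though they agree to
first order in the relative changes. Group differences are tested with
the Wilcoxon rank-sum on per-plant averages: midranks for ties, exact
enumeration of all rank assignments for combined n ≤ 12 (feasible and
matching the small cohort sizes), tie-corrected normal approximation
with continuity correction beyond.

## Synthetic data

Ring profiles: a k-period cosine plus optional planted incipient peaks
plus Gaussian noise (Gaussian, unlike the simulation's uniform initial
noise, because quantification tests need a controllable SNR). Incipient
peaks are single-cell bumps at trough centers whose height is solved to
sit midway between detectability (above both flanking values) and the
0.15 ceiling, so the filter removes exactly them in the noiseless case.
With noise, exact per-profile recovery of k requires SNR
(amplitude/noise-sd) ≳ 20 — near the flat cosine tops small noise can
split a peak in two — while the median count over replicates recovers k
from SNR 10. Cohorts: V and λ_k are symmetric rounded-normal draws
around the group medians (min 2 cells per unit, min 1 unit), so sample
medians converge to the planted medians and every section satisfies the
V = N/λ identity by construction.

What the generators do not emulate: real cross sections have correlated
unit sizes around the ring, non-symmetric dispersion and measurement
error in cell counting; simulated rings differ from real tissue in
having fixed cell number, one spatial dimension and no growth. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic
and the model's internal consistency, not fidelity of the biology.

## Problem sizes

Unit tests run on rings of 6–60 cells with short horizons; the
full-size property suite uses 60-cell rings, 30 replicates per
condition, t_end = 17.5 at dt = 1e−4, 20-point phase grids with 5 seeds
each, exhaustive enumeration up to ring length 8, and 500–1000 random
cases for the statistical oracles. The acceptance script reruns the
four-point influx sweep at 30 replicates.

## Known limitations

- The phase boundary's absolute position depends on the calibrated
  effective parameters (ρ, w, ν_c); only its qualitative structure is
  constrained.
- The closed-form approximations to the stability boundary are not
  implemented; the numeric analysis is the single source of truth.
- Flux kinetics are linear by design; saturating (Michaelis–Menten)
  transport is out of scope, as are 2-D/3-D geometries, growth, division
  and stochastic dynamics (noise enters only the initial condition).
- κ from simulation is slightly below the linear prediction at high
  influx (nonlinear coarsening merges peaks after onset); the two agree
  within one mode at most sweep points.
- The ensemble-median cytosolic average-maxima level is not monotone in
  influx under the calibrated defaults: it dips at intermediate I where
  the selected mode count rises (fewer peaks at low influx concentrate
  the same auxin mass into taller maxima), although the end-to-end
  increase from the lowest to the highest influx holds. The apoplastic
  trends (mean and amplitude falling with influx, mean rising with
  efflux) are monotone as expected.
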