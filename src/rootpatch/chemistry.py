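"""Auxin source–sink diffusion and ROP activation dynamics.

The cell surface is discretized into polygonal compartments
(:class:`~rootpatch.geometry.CellDomain2D`). Auxin A obeys

    dA/dt = D_a ΔA + t + s_in·[source] − s_out·A·[sink] − q·A

with the source strip at the basal end and the sink strip at the apical end.
ROP cycles between a slow-diffusing, membrane-bound active form R_a and a
fast cytosolic inactive form R_i:

    dR_a/dt = D_1 ΔR_a + a + R_i (k_1 + k_2 R_a² A) − c R_a − (r + p·[boundary]) R_a
    dR_i/dt = D_2 ΔR_i + b − e R_i − R_i (k_1 + k_2 R_a² A) + c R_a

The auxin-dependent autocatalytic activation (k_2 R_a² A) together with the
fast/slow diffusion contrast produces a localized patch of active ROP; the
auxin gradient biases its position toward the basal end. Δ is the discrete
compartment Laplacian with zero-flux outer boundary; the only boundary loss
channel is the explicit degradation rate p in boundary compartments.

Concentration and length units are the arbitrary model units of the rate
table; the default elongated cell is 10 × 2 length units.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import scipy.sparse as sp

from .geometry import CellDomain2D

#: Default cell geometry (length, width, compartments) in model units.
DEFAULT_CELL = dict(length=10.0, width=2.0, n_compartments=286)


class ConvergenceError(RuntimeError):
    """Steady state not reached within the allotted simulated time."""

    def __init__(self, msg: str, residual: float = np.nan):
        super().__init__(msg)
        self.residual = residual


class StepSizeError(RuntimeError):
    """The explicit integrator became unstable (non-finite state)."""


@dataclass(frozen=True)
class ChemParams:
    """Rate constants of the auxin and ROP models (model units).

    Defaults are the gradient-mode values of the reference rate table;
    ``constant_auxin`` switches to the spatially uniform auxin regime where
    only general production ``t`` and degradation ``q = 0.1`` act.
    """

    D_a: float = 5.0       # auxin diffusion, length²/s
    t: float = 0.0         # general auxin production, conc/s
    s_in: float = 0.25     # source production, conc/s
    s_out: float = 0.31    # sink degradation, 1/s
    q: float = 2.0e-5      # auxin degradation, 1/s
    D_1: float = 0.01      # active ROP diffusion, length²/s
    D_2: float = 1.0       # inactive ROP diffusion, length²/s
    a: float = 0.0         # active ROP production, conc/s
    b: float = 0.01        # inactive ROP production, conc/s
    c: float = 0.1         # inactivation, 1/s
    e: float = 0.0         # inactive ROP degradation, 1/s
    r: float = 0.01        # active ROP degradation, 1/s
    p: float = 0.01        # boundary degradation of active ROP, 1/s
    k_1: float = 0.01      # constant activation, 1/s
    k_2: float = 0.015     # auxin-dependent autoactivation, 1/(conc³·s)

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be non-negative")

    @classmethod
    def constant_auxin(cls, t: float, q: float = 0.1) -> "ChemParams":
        """Uniform-auxin regime: steady auxin level is t/q everywhere."""
        return cls(t=t, q=q, s_in=0.0, s_out=0.0)


@dataclass
class ChemState:
    """Per-compartment concentrations at a time point."""

    A: np.ndarray
    R_a: np.ndarray
    R_i: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, n: int) -> "ChemState":
        return cls(A=np.zeros(n), R_a=np.zeros(n), R_i=np.zeros(n))


@dataclass
class PatchSummary:
    """Detected active-ROP patches and position of the dominant one."""

    n_peaks: int
    peaks: list[tuple[tuple[float, float], float, float]]
    basal_offset: float = np.nan     # dominant-peak centroid x / cell length
    lateral_offset: float = np.nan   # signed (centroid y − midline) / width


# ---------------------------------------------------------------------------
# Spatial operator
# ---------------------------------------------------------------------------

def laplacian_matrix(domain: CellDomain2D) -> sp.csr_matrix:
    """Unit-diffusivity discrete Laplacian L with
    (L f)_i = (1/area_i) Σ_j (L_ij/d_ij)(f_j − f_i), zero-flux at the border."""
    i, j, w = domain.conductances()
    n = domain.n
    M = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    M = M - sp.diags(np.asarray(M.sum(axis=1)).ravel())
    return sp.diags(1.0 / domain.areas) @ M


def discrete_laplacian(domain: CellDomain2D, field: np.ndarray, D: float) -> np.ndarray:
    """Diffusive rate D·Δfield per compartment (conc/s)."""
    field = np.asarray(field, dtype=float)
    if field.shape != (domain.n,):
        raise ValueError("field must be defined on every compartment")
    return D * (laplacian_matrix(domain) @ field)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def auxin_rhs(domain: CellDomain2D, state: ChemState, params: ChemParams,
              _lap: sp.csr_matrix | None = None) -> np.ndarray:
    lap = laplacian_matrix(domain) if _lap is None else _lap
    A = state.A
    rhs = params.D_a * (lap @ A) + params.t - params.q * A
    rhs = rhs + params.s_in * domain.source_mask
    rhs = rhs - params.s_out * A * domain.sink_mask
    return rhs


def rop_rhs(domain: CellDomain2D, state: ChemState, params: ChemParams,
            _lap: sp.csr_matrix | None = None) -> tuple[np.ndarray, np.ndarray]:
    if np.any(state.R_a < 0) or np.any(state.R_i < 0):
        raise ValueError("negative ROP concentrations in input state")
    lap = laplacian_matrix(domain) if _lap is None else _lap
    A, Ra, Ri = state.A, state.R_a, state.R_i
    activation = Ri * (params.k_1 + params.k_2 * Ra**2 * A)
    decay = params.r + params.p * domain.boundary_mask
    dRa = params.D_1 * (lap @ Ra) + params.a + activation - params.c * Ra - decay * Ra
    dRi = (params.D_2 * (lap @ Ri) + params.b - params.e * Ri
           - activation + params.c * Ra)
    return dRa, dRi


def auxin_steady_state_direct(domain: CellDomain2D, params: ChemParams) -> np.ndarray:
    """Steady auxin field by direct sparse solve of the (linear) balance.

    Solves D_a ΔA + t + s_in·[source] = (q + s_out·[sink])·A. Useful as an
    independent check on the time-stepped equilibrium.
    """
    from scipy.sparse.linalg import spsolve

    lap = laplacian_matrix(domain)
    M = params.D_a * lap - sp.diags(params.q + params.s_out * domain.sink_mask.astype(float))
    rhs = np.full(domain.n, -params.t) - params.s_in * domain.source_mask
    return spsolve(M.tocsc(), rhs)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def stable_dt(domain: CellDomain2D, D_max: float, safety: float = 0.5) -> float:
    """Fixed step below the explicit diffusive stability bound."""
    i, j, w = domain.conductances()
    rate = np.zeros(domain.n)
    np.add.at(rate, i, w)
    rate = D_max * rate / domain.areas
    return safety * 2.785 / rate.max()   # RK4 real-axis stability limit


def initial_rop_state(domain: CellDomain2D, A: np.ndarray,
                      level: float = 0.1, noise: float = 0.01,
                      seed: int = 0) -> ChemState:
    """R_a = 0, R_i = small uniform level with multiplicative noise.

    The noise breaks lateral symmetry, which is required for patch
    formation under spatially constant auxin.
    """
    rng = np.random.default_rng(seed)
    Ri = level * (1.0 + noise * rng.uniform(-1, 1, domain.n))
    return ChemState(A=A.copy(), R_a=np.zeros(domain.n), R_i=Ri)


def equilibrium_rop_state(domain: CellDomain2D, A: np.ndarray,
                          noise: float = 0.01, seed: int = 0,
                          params: ChemParams | None = None) -> ChemState:
    """Uniform reaction equilibrium of the ROP system plus small noise.

    With production only of the inactive form and degradation only of the
    active form, the interior balance fixes R_a* = b/r and
    R_i* = (c + r)·R_a* / (k_1 + k_2·R_a*²·A). Starting the patterning run
    from this homogeneous state (perturbed multiplicatively by ``noise``)
    probes the instability of the uniform state directly, so several peaks
    can nucleate simultaneously where the uniform state is Turing-unstable.
    """
    p = params or ChemParams()
    if p.r <= 0:
        raise ValueError("equilibrium init requires r > 0")
    rng = np.random.default_rng(seed)
    Ra0 = p.b / p.r
    act = p.k_1 + p.k_2 * Ra0**2 * np.asarray(A, dtype=float)
    Ri0 = (p.c + p.r) * Ra0 / act
    pert = 1.0 + noise * rng.uniform(-1, 1, domain.n)
    return ChemState(A=np.asarray(A, dtype=float).copy(),
                     R_a=np.full(domain.n, Ra0), R_i=Ri0 * pert)


def integrate_to_steady_state(
    domain: CellDomain2D,
    params: ChemParams,
    initial: ChemState,
    which: str,
    dt: float | None = None,
    tol: float = 1e-8,
    max_time: float = 2.0e5,
    check_every: int = 50,
    on_max_time: str = "raise",
) -> ChemState:
    """Classical fixed-step RK4 to equilibrium.

    ``which='auxin'`` evolves A only; ``which='rop'`` evolves (R_a, R_i)
    with the A field held fixed (the auxin simulation is run first and its
    steady gradient is frozen into the ROP run). Terminates when
    max |d·/dt| < tol for every evolved species. At ``max_time`` it either
    raises :class:`ConvergenceError` (``on_max_time='raise'``) or returns
    the final state (``on_max_time='return'``; useful for parameter regimes
    whose attractor is oscillatory rather than stationary).
    """
    if on_max_time not in ("raise", "return"):
        raise ValueError("on_max_time must be 'raise' or 'return'")
    if which not in ("auxin", "rop"):
        raise ValueError("which must be 'auxin' or 'rop'")
    lap = laplacian_matrix(domain)
    if dt is None:
        D_max = params.D_a if which == "auxin" else max(params.D_1, params.D_2)
        dt = stable_dt(domain, max(D_max, 1e-12))
    if dt <= 0:
        raise ValueError("dt must be positive")

    state = ChemState(initial.A.copy(), initial.R_a.copy(), initial.R_i.copy(),
                      initial.time)

    # RHS closures over plain arrays: the generic per-operation entry points
    # (auxin_rhs / rop_rhs) are equivalent but too slow for the inner loop.
    if which == "auxin":
        DaLap = (params.D_a * lap).tocsr()
        production = params.t + params.s_in * domain.source_mask
        decay = params.q + params.s_out * domain.sink_mask

        def f(y):
            return DaLap @ y + production - decay * y
        y = state.A
    else:
        if np.any(state.R_a < 0) or np.any(state.R_i < 0):
            raise ValueError("negative ROP concentrations in initial state")
        D1Lap = (params.D_1 * lap).tocsr()
        D2Lap = (params.D_2 * lap).tocsr()
        k2A = params.k_2 * state.A
        ra_decay = params.c + params.r + params.p * domain.boundary_mask

        def f(y):
            Ra, Ri = y
            act = Ri * (params.k_1 + k2A * Ra * Ra)
            dRa = D1Lap @ Ra + params.a + act - ra_decay * Ra
            dRi = D2Lap @ Ri + params.b - params.e * Ri - act + params.c * Ra
            return np.stack([dRa, dRi])
        y = np.stack([state.R_a, state.R_i])

    t, steps = state.time, 0
    residual = np.inf
    while t < state.time + max_time:
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        steps += 1
        if not np.all(np.isfinite(y)):
            raise StepSizeError(f"integration diverged at t={t:.3g} (dt={dt:.3g})")
        if steps % check_every == 0:
            residual = np.abs(f(y)).max()
            if residual < tol:
                break
    else:
        if on_max_time == "raise":
            raise ConvergenceError(
                f"no steady state by t={t:.3g}; residual {residual:.3g}",
                residual)

    if which == "auxin":
        return ChemState(A=y, R_a=state.R_a, R_i=state.R_i, time=t)
    return ChemState(A=state.A, R_a=y[0], R_i=y[1], time=t)


# ---------------------------------------------------------------------------
# Readouts
# ---------------------------------------------------------------------------

@dataclass
class PatterningResult:
    """Outcome of a full two-stage (auxin → ROP) patterning simulation."""

    domain: CellDomain2D
    state: ChemState
    summary: "PatchSummary"
    gradient_percent: float | None = None
    mode: str = "gradient"
    converged: bool = True


def simulate_patterning(
    mode: str = "gradient",
    auxin_level: float = 1.2,
    length: float = DEFAULT_CELL["length"],
    width: float = DEFAULT_CELL["width"],
    n_compartments: int = DEFAULT_CELL["n_compartments"],
    source_fraction: float = 0.05,
    sink_fraction: float = 0.05,
    geometry_seed: int = 1,
    seed: int = 0,
    noise: float = 0.01,
    params: ChemParams | None = None,
    tol: float = 1e-8,
    rel_threshold: float = 0.5,
    max_time: float | None = None,
) -> PatterningResult:
    """Run the auxin stage and then the ROP stage to steady state.

    ``mode='gradient'`` uses the source–sink auxin model. Because the
    problem is mirror symmetric about the lateral midline while the
    patterning instability amplifies any numerical asymmetry, the gradient
    run is computed on the symmetry-reduced half cell (no-flux at the
    midline, boundary degradation only on true membrane edges) and the
    fields are reflected onto the full symmetric tessellation. The lateral
    patch position is then set by the model, not by discretization noise.

    ``mode='constant'`` simulates a spatially uniform auxin level
    (production t = level·q, q = 0.1) on the full tessellation, starting
    from the uniform reaction equilibrium perturbed by multiplicative noise
    (amplitude ``noise``, generator ``seed``); peak positions are
    noise-dependent. Above A ≈ 1.09 the uniform state is Hopf-unstable, so
    on cells shorter than the stationary-pattern wavelength (≈ 11.5 length
    units) the constant-auxin dynamics are oscillatory and no steady state
    exists; the run then stops at ``max_time`` (default 2·10⁴ s) and returns
    the final state with ``converged=False``.
    """
    from .geometry import build_cell_domain, mark_boundary

    if mode == "gradient":
        chem = params or ChemParams()
        half = build_cell_domain(length, width / 2, n_compartments // 2,
                                 source_fraction, sink_fraction,
                                 seed=geometry_seed, symmetric=False)
        mark_boundary(half, ("x0", "x1", "y0"))
        aux = integrate_to_steady_state(
            half, chem, ChemState.zeros(half.n), "auxin", tol=tol,
            max_time=max_time or 2.0e5)
        init = initial_rop_state(half, aux.A, noise=noise, seed=seed)
        rop = integrate_to_steady_state(half, chem, init, "rop", tol=tol,
                                        max_time=max_time or 2.0e5)
        full = build_cell_domain(length, width, n_compartments,
                                 source_fraction, sink_fraction,
                                 seed=geometry_seed, symmetric=True)
        state = ChemState(A=np.repeat(aux.A, 2), R_a=np.repeat(rop.R_a, 2),
                          R_i=np.repeat(rop.R_i, 2), time=rop.time)
        grad = auxin_gradient_percent(state, full)
        return PatterningResult(full, state, detect_patches(state, full,
                                                            rel_threshold),
                                gradient_percent=grad, mode=mode)

    if mode != "constant":
        raise ValueError("mode must be 'gradient' or 'constant'")
    chem = params or ChemParams.constant_auxin(t=auxin_level * 0.1)
    full = build_cell_domain(length, width, n_compartments,
                             source_fraction, sink_fraction,
                             seed=geometry_seed, symmetric=True)
    aux = integrate_to_steady_state(
        full, chem, ChemState.zeros(full.n), "auxin", tol=tol)
    init = equilibrium_rop_state(full, aux.A, noise=noise, seed=seed,
                                 params=chem)
    rop = integrate_to_steady_state(full, chem, init, "rop", tol=tol,
                                    max_time=max_time or 2.0e4,
                                    on_max_time="return")
    state = ChemState(A=aux.A, R_a=rop.R_a, R_i=rop.R_i, time=rop.time)
    dRa, dRi = rop_rhs(full, state, chem)
    converged = max(np.abs(dRa).max(), np.abs(dRi).max()) < tol
    return PatterningResult(full, state,
                            detect_patches(state, full, rel_threshold),
                            gradient_percent=None, mode=mode,
                            converged=converged)


def auxin_gradient_percent(state: ChemState, domain: CellDomain2D,
                           strip_fraction: float = 0.1) -> float:
    """Relative basal-to-apical auxin drop, in percent.

    Area-weighted mean auxin over the basal-most and apical-most strips
    (default 10% of cell length each): 100·(Ā_basal − Ā_apical)/Ā_basal.
    """
    x = domain.centroids[:, 0]
    areas = domain.areas
    basal = x <= strip_fraction * domain.length
    apical = x >= (1 - strip_fraction) * domain.length
    A_b = np.average(state.A[basal], weights=areas[basal])
    A_a = np.average(state.A[apical], weights=areas[apical])
    return 100.0 * (A_b - A_a) / A_b


def detect_patches(state: ChemState, domain: CellDomain2D,
                   rel_threshold: float = 0.5,
                   min_contrast: float = 2.0) -> PatchSummary:
    """Cluster above-threshold compartments into active-ROP patches.

    Compartments with R_a ≥ rel_threshold·max(R_a) are grouped by adjacency
    into connected clusters. A near-uniform field is not a patch: detection
    requires max(R_a) ≥ min_contrast × area-weighted mean(R_a), otherwise no
    peaks are reported. The dominant peak (largest integrated active ROP)
    defines the basal and lateral offsets.
    """
    if not (0 < rel_threshold < 1):
        raise ValueError("rel_threshold must be in (0, 1)")
    Ra = state.R_a
    mx = Ra.max() if Ra.size else 0.0
    mean = np.average(Ra, weights=domain.areas) if Ra.size else 0.0
    if mx <= 0 or (mean > 0 and mx < min_contrast * mean):
        return PatchSummary(n_peaks=0, peaks=[])

    above = Ra >= rel_threshold * mx
    i, j, _ = domain.conductances()
    mask = above[i] & above[j]
    n = domain.n
    adj = sp.coo_matrix((np.ones(mask.sum()), (i[mask], j[mask])), shape=(n, n))
    n_comp, labels = sp.csgraph.connected_components(adj.tocsr(), directed=False)

    areas, cents = domain.areas, domain.centroids
    peaks = []
    for lab in range(n_comp):
        members = np.flatnonzero((labels == lab) & above)
        if members.size == 0:
            continue
        w = Ra[members] * areas[members]
        centroid = tuple(np.average(cents[members], axis=0, weights=w))
        peaks.append((centroid, float(Ra[members].max()), float(w.sum())))
    peaks.sort(key=lambda pk: -pk[2])

    if not peaks:
        return PatchSummary(n_peaks=0, peaks=[])
    (px, py), _, _ = peaks[0]
    return PatchSummary(
        n_peaks=len(peaks),
        peaks=peaks,
        basal_offset=px / domain.length,
        lateral_offset=(py - 0.5 * domain.width) / domain.width,
    )
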