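"""Radial/circumferential stress-pattern analysis around the wall patch.

The mechanical hypothesis distinguishes two stress organizations around the
root hair initiation site: *circumferential* (maximal principal stress
wrapping around the site, as around loosened regions in diffuse growth) and
*radial* (star-like, matching the microtubule pattern observed at initiation
sites). The classifier is the ratio of the radial to the circumferential
Cauchy stress component in a polar frame centred on the site: ratio < 1 →
circumferential, ratio > 1 → radial.

Sample points sit just outside the modified circular region. Averaging the
+x-axis point with the +45° diagonal point cancels most of the angular
anisotropy of the square domain (the clamped square edges bias σ_rr upward
on the axes and downward on the diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ShellMesh, build_shell_mesh
from .mechanics import (KinematicState, LoadField, MaterialParams,
                        SolverOptions, StressField, cauchy_and_principal,
                        solve_equilibrium)

#: Wall-patch geometry defaults (μm): 20×20 square, 0.5 thick, central
#: circular region of radius 2.
DEFAULT_WALL = dict(side=20.0, thickness=0.5, patch_center=(10.0, 10.0),
                    patch_radius=2.0, n_elements_per_side=40)

#: The five perturbation scenarios plus the homogeneous baseline
#: (inner Young's modulus in MPa, inner turgor in MPa).
SCENARIOS = {
    "baseline": dict(E_inner=100.0, p_inner=0.2),
    "soft": dict(E_inner=70.0, p_inner=0.2),
    "stiff": dict(E_inner=130.0, p_inner=0.2),
    "pressure": dict(E_inner=100.0, p_inner=0.4),
    "pressure_soft": dict(E_inner=70.0, p_inner=0.4),
    "pressure_stiff": dict(E_inner=130.0, p_inner=0.4),
}

E_OUTER = 100.0
NU = 0.2
P_OUTER = 0.2

#: Sample points sit this far outside the circular region boundary (μm).
SAMPLE_OFFSET = 1.0


@dataclass
class RatioResult:
    """Radial-to-circumferential stress ratios at sample points."""

    sample_points: list[tuple[float, float]]
    ratios: np.ndarray
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    non_tensile: np.ndarray          # flags σ_θθ <= 0 per point
    classification: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.classification:
            self.classification = [
                "radial" if r > 1 else "circumferential" for r in self.ratios]

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def mean_classification(self) -> str:
        return "radial" if self.mean_ratio > 1 else "circumferential"


def default_sample_points(center: tuple[float, float], patch_radius: float,
                          offset: float = SAMPLE_OFFSET) -> list[tuple[float, float]]:
    """Two points outside the region rim: on the +x axis and the +45° diagonal."""
    r = patch_radius + offset
    cx, cy = center
    return [(cx + r, cy), (cx + r / np.sqrt(2), cy + r / np.sqrt(2))]


def polar_stress_ratio(stress: StressField, center: tuple[float, float],
                       points: list[tuple[float, float]],
                       averaging_radius: float,
                       outer_only: bool = True) -> RatioResult:
    """σ_rr / σ_θθ in the polar frame about ``center`` at each sample point.

    For every element whose reference centroid lies within
    ``averaging_radius`` of the point, the radial unit vector is projected
    onto the element's deformed tangent plane (the circumferential direction
    is its in-plane normal); the component averages over the neighbourhood
    give the ratio. σ_θθ ≤ 0 is reported via ``non_tensile`` rather than
    dropped.
    """
    cx, cy = center
    cents = stress.centroids
    ratios, srr_out, stt_out, flags = [], [], [], []
    for (px, py) in points:
        d = np.hypot(cents[:, 0] - px, cents[:, 1] - py)
        sel = d <= averaging_radius
        if outer_only and stress.mesh is not None:
            sel &= stress.mesh.region_label == "outer"
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            idx = np.array([np.argmin(d)])
        srr = stt = 0.0
        for e in idx:
            sig = stress.sigma[e]
            n = np.cross(stress.dir_1[e], stress.dir_2[e])
            n /= np.linalg.norm(n)
            rhat = np.array([cents[e, 0] - cx, cents[e, 1] - cy, 0.0])
            rhat /= np.linalg.norm(rhat)
            t_r = rhat - (rhat @ n) * n
            t_r /= np.linalg.norm(t_r)
            t_t = np.cross(n, t_r)
            srr += t_r @ sig @ t_r
            stt += t_t @ sig @ t_t
        srr /= idx.size
        stt /= idx.size
        srr_out.append(srr)
        stt_out.append(stt)
        flags.append(stt <= 0)
        ratios.append(srr / stt if stt > 0 else np.inf)
    return RatioResult(sample_points=list(points), ratios=np.array(ratios),
                       sigma_rr=np.array(srr_out), sigma_tt=np.array(stt_out),
                       non_tensile=np.array(flags))


def _materials(E_inner: float, nu: float = NU) -> dict[str, MaterialParams]:
    return {"inner": MaterialParams(E_inner, nu),
            "outer": MaterialParams(E_OUTER, nu)}


def run_scenario(name: str,
                 mesh: ShellMesh | None = None,
                 E_inner: float | None = None,
                 p_inner: float | None = None,
                 options: SolverOptions | None = None,
                 sample_offset: float = SAMPLE_OFFSET,
                 ) -> tuple[KinematicState, StressField, RatioResult]:
    """Solve one named scenario and classify the surrounding stress pattern.

    Scenario parameters can be overridden; the mesh defaults to the standard
    20×20 μm patch with a 2 μm central region.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario '{name}'; choose from {list(SCENARIOS)}")
    cfg = dict(SCENARIOS[name])
    if E_inner is not None:
        cfg["E_inner"] = E_inner
    if p_inner is not None:
        cfg["p_inner"] = p_inner
    if mesh is None:
        mesh = build_shell_mesh(**DEFAULT_WALL)
    state = solve_equilibrium(mesh, _materials(cfg["E_inner"]),
                              LoadField(P_OUTER, cfg["p_inner"]), options)
    stress = cauchy_and_principal(state)
    pts = default_sample_points(mesh.patch_center, mesh.patch_radius,
                                offset=sample_offset)
    avg_r = mesh.side / max(len(mesh.quads), 1) ** 0.5  # ≈ one element size
    ratio = polar_stress_ratio(stress, mesh.patch_center, pts, avg_r)
    return state, stress, ratio


def modulus_sweep(E_inner_values, mesh: ShellMesh | None = None,
                  options: SolverOptions | None = None) -> pd.DataFrame:
    """Ratio vs. inner-region Young's modulus at fixed 0.2 MPa turgor."""
    return _sweep([("E_inner", E, P_OUTER) for E in E_inner_values],
                  mesh, options)


def pressure_sweep(p_inner_values, E_inner: float = 70.0,
                   mesh: ShellMesh | None = None,
                   options: SolverOptions | None = None) -> pd.DataFrame:
    """Ratio vs. inner-region turgor with a softened centre (default 70 MPa)."""
    return _sweep([("p_inner", E_inner, p) for p in p_inner_values],
                  mesh, options)


def _sweep(cases, mesh, options) -> pd.DataFrame:
    if mesh is None:
        mesh = build_shell_mesh(**DEFAULT_WALL)
    pts = default_sample_points(mesh.patch_center, mesh.patch_radius)
    avg_r = mesh.side / max(len(mesh.quads), 1) ** 0.5
    rows = []
    for varied, E_in, p_in in cases:
        state = solve_equilibrium(mesh, _materials(E_in),
                                  LoadField(P_OUTER, p_in), options)
        stress = cauchy_and_principal(state)
        rr = polar_stress_ratio(stress, mesh.patch_center, pts, avg_r)
        for k, (pt, ratio, srr, stt) in enumerate(
                zip(rr.sample_points, rr.ratios, rr.sigma_rr, rr.sigma_tt)):
            rows.append(dict(varied=varied, E_inner=E_in, p_inner=p_in,
                             point=k, x=pt[0], y=pt[1],
                             sigma_rr=srr, sigma_tt=stt, ratio=ratio,
                             classification="radial" if ratio > 1
                             else "circumferential"))
        rows.append(dict(varied=varied, E_inner=E_in, p_inner=p_in,
                         point=-1, x=np.nan, y=np.nan,
                         sigma_rr=rr.sigma_rr.mean(), sigma_tt=rr.sigma_tt.mean(),
                         ratio=rr.mean_ratio,
                         classification=rr.mean_classification))
    return pd.DataFrame(rows)


def plot_principal_directions(stress: StressField, path,
                              subsample: int = 2) -> None:
    """Quiver-style export of principal stress directions.

    White bars mark the maximal, black bars the minimal principal direction;
    the background color shows the maximal stress magnitude.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cents = stress.centroids[::subsample]
    mag = stress.max_magnitude
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.tripcolor(stress.centroids[:, 0], stress.centroids[:, 1], mag,
                      shading="gouraud", cmap="viridis")
    for d, color in ((stress.dir_1[::subsample], "white"),
                     (stress.dir_2[::subsample], "black")):
        ax.quiver(cents[:, 0], cents[:, 1], d[:, 0], d[:, 1],
                  color=color, pivot="mid", scale=45, headwidth=1,
                  headlength=0, headaxislength=0, width=0.003)
    fig.colorbar(sc, ax=ax, label="max principal stress (MPa)")
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def deflection_contrast(soft_state: KinematicState,
                        stiff_state: KinematicState) -> float:
    """w_center(soft) − w_center(stiff), μm; positive = softening bulges out."""
    m1, m2 = soft_state.mesh, soft_state.mesh and stiff_state.mesh
    if (m1 is None or m2 is None or len(m1.nodes) != len(m2.nodes)
            or not np.allclose(m1.nodes, m2.nodes)):
        raise ValueError("states must be solved on the same mesh")
    c = np.asarray(m1.patch_center)
    i = np.argmin(np.hypot(m1.nodes[:, 0] - c[0], m1.nodes[:, 1] - c[1]))
    return float(soft_state.displacements[i, 2] - stiff_state.displacements[i, 2])
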