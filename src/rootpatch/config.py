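"""Scenario configuration and the end-to-end pipeline.

A single YAML document configures all stages. Every key has a default that
reproduces the headline runs (rate-table chemistry on the 286-compartment
cell; 20×20 μm wall patch at 0.2/0.4 MPa turgor with 70/100/130 MPa
regions), so an empty config is a complete experiment description.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, chemistry, mechanics, vtkio
from .geometry import build_cell_domain, build_shell_mesh

log = logging.getLogger("rootpatch")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class CellGeometryConfig:
    length: float = chemistry.DEFAULT_CELL["length"]
    width: float = chemistry.DEFAULT_CELL["width"]
    n_compartments: int = chemistry.DEFAULT_CELL["n_compartments"]
    source_fraction: float = 0.05
    sink_fraction: float = 0.05
    seed: int = 1
    symmetric: bool = True


@dataclass
class WallGeometryConfig:
    side: float = 20.0
    thickness: float = 0.5
    patch_center: tuple = (10.0, 10.0)
    patch_radius: float = 2.0
    n_elements_per_side: int = 40
    conform: bool = False


@dataclass
class ChemistryConfig:
    mode: str = "gradient"
    auxin_level: float = 1.2
    seed: int = 0
    noise: float = 0.01
    tol: float = 1e-8
    rel_threshold: float = 0.5
    #: overrides for individual rate constants, keyed by their symbols
    params: dict = field(default_factory=dict)

    def chem_params(self) -> chemistry.ChemParams | None:
        if not self.params:
            return None
        base = (chemistry.ChemParams() if self.mode == "gradient"
                else chemistry.ChemParams.constant_auxin(self.auxin_level * 0.1))
        valid = set(asdict(base))
        unknown = set(self.params) - valid
        if unknown:
            raise ConfigError(f"unknown rate constants: {sorted(unknown)}")
        return chemistry.ChemParams(**{**asdict(base), **self.params})


@dataclass
class MechanicsConfig:
    scenario: str = "baseline"
    E_inner: float | None = None
    E_outer: float = analysis.E_OUTER
    nu: float = 0.2
    p_inner: float | None = None
    p_outer: float = analysis.P_OUTER
    n_load_steps: int = 10
    rtol: float = 1e-8
    max_iterations: int = 50

    def solver_options(self) -> mechanics.SolverOptions:
        return mechanics.SolverOptions(n_load_steps=self.n_load_steps,
                                       rtol=self.rtol,
                                       max_iterations=self.max_iterations)


@dataclass
class AnalysisConfig:
    sample_offset: float = analysis.SAMPLE_OFFSET
    modulus_values: list = field(
        default_factory=lambda: [60.0, 73.3, 86.7, 100.0, 113.3, 126.7, 140.0])
    pressure_values: list = field(
        default_factory=lambda: [0.2, 0.233, 0.267, 0.3, 0.333, 0.367, 0.4])


@dataclass
class ScenarioConfig:
    cell: CellGeometryConfig = field(default_factory=CellGeometryConfig)
    wall: WallGeometryConfig = field(default_factory=WallGeometryConfig)
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "rootpatch_out"
    version: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "cell": CellGeometryConfig,
    "wall": WallGeometryConfig,
    "chemistry": ChemistryConfig,
    "mechanics": MechanicsConfig,
    "analysis": AnalysisConfig,
}


def load_config(path=None, overrides: dict | None = None) -> ScenarioConfig:
    """Read and validate a YAML config; missing keys take the built-in defaults,
    unknown keys raise :class:`ConfigError` naming the key."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
    if overrides:
        raw = _deep_merge(raw, overrides)

    cfg = ScenarioConfig()
    for key, value in raw.items():
        if key == "version":
            cfg.version = int(value)
        elif key == "output_dir":
            cfg.output_dir = str(value)
        elif key in _SECTIONS:
            section = getattr(cfg, key)
            known = set(asdict(section))
            for k, v in (value or {}).items():
                if k not in known:
                    raise ConfigError(f"unknown key '{key}.{k}'")
                if k == "patch_center":
                    v = tuple(v)
                setattr(section, k, v)
        else:
            raise ConfigError(f"unknown config section '{key}'")
    _validate(cfg)
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate(cfg: ScenarioConfig) -> None:
    if cfg.chemistry.mode not in ("gradient", "constant"):
        raise ConfigError("chemistry.mode must be 'gradient' or 'constant'")
    if cfg.mechanics.scenario not in analysis.SCENARIOS:
        raise ConfigError(
            f"mechanics.scenario must be one of {sorted(analysis.SCENARIOS)}")
    if not 0 <= cfg.mechanics.nu < 0.5:
        raise ConfigError("mechanics.nu must lie in [0, 0.5)")
    cfg.chemistry.chem_params()   # raises on unknown rate symbols
    for p in (cfg.mechanics.p_inner, cfg.mechanics.p_outer):
        if p is not None and p < mechanics.ATMOSPHERE_MPA:
            raise ConfigError("turgor pressures must exceed 1 atm")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: ScenarioConfig,
                 stages: tuple[str, ...] = ("mesh", "rop", "solve", "analyze"),
                 ) -> dict:
    """Execute the requested stages in order, writing all artifacts under
    ``cfg.output_dir``. Returns the summary dictionary (also written as
    ``summary.json``)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": list(stages)}

    mesh = None
    if {"mesh", "solve", "analyze"} & set(stages):
        t0 = time.perf_counter()
        domain = build_cell_domain(**asdict(cfg.cell))
        mesh = build_shell_mesh(**{**asdict(cfg.wall),
                                   "patch_center": tuple(cfg.wall.patch_center)})
        if "mesh" in stages:
            vtkio.write_cell_domain_vtk(domain, out / "cell_domain.vtk")
            vtkio.write_polygon_list(domain, out / "cell_polygons.txt")
            vtkio.write_shell_mesh_vtk(mesh, out / "wall_mesh.vtk")
        log.info("mesh stage: %d compartments, %d elements (%.2fs)",
                 domain.n, mesh.n_elements, time.perf_counter() - t0)
        summary["n_compartments"] = domain.n
        summary["n_elements"] = mesh.n_elements

    if "rop" in stages:
        t0 = time.perf_counter()
        ch = cfg.chemistry
        res = chemistry.simulate_patterning(
            mode=ch.mode, auxin_level=ch.auxin_level,
            length=cfg.cell.length, width=cfg.cell.width,
            n_compartments=cfg.cell.n_compartments,
            source_fraction=cfg.cell.source_fraction,
            sink_fraction=cfg.cell.sink_fraction,
            geometry_seed=cfg.cell.seed, seed=ch.seed, noise=ch.noise,
            params=ch.chem_params(), tol=ch.tol,
            rel_threshold=ch.rel_threshold)
        vtkio.write_compartment_csv(res.domain, res.state,
                                    out / "compartments.csv")
        vtkio.write_cell_domain_vtk(res.domain, out / "cell_fields.vtk",
                                    res.state)
        extra = {"mode": res.mode, "converged": bool(res.converged)}
        if res.gradient_percent is not None:
            extra["auxin_gradient_percent"] = res.gradient_percent
        vtkio.write_patch_summary_json(res.summary,
                                       out / "patch_summary.json", extra)
        log.info("rop stage: %d peak(s), t=%.0f s model time (%.1fs)",
                 res.summary.n_peaks, res.state.time, time.perf_counter() - t0)
        summary["rop"] = {"n_peaks": res.summary.n_peaks,
                          "basal_offset": res.summary.basal_offset,
                          "lateral_offset": res.summary.lateral_offset,
                          **extra}

    if {"solve", "analyze"} & set(stages):
        t0 = time.perf_counter()
        mech = cfg.mechanics
        state, stress, ratio = analysis.run_scenario(
            mech.scenario, mesh=mesh, E_inner=mech.E_inner,
            p_inner=mech.p_inner, options=mech.solver_options(),
            sample_offset=cfg.analysis.sample_offset)
        vtkio.write_shell_mesh_vtk(mesh, out / "solution.vtk",
                                   displacements=state.displacements,
                                   stress_field=stress)
        vtkio.write_stress_csv(stress, out / "stress.csv")
        log.info("solve stage: scenario '%s', max |w| = %.3f um (%.1fs)",
                 mech.scenario, np.abs(state.displacements[:, 2]).max(),
                 time.perf_counter() - t0)
        summary["solve"] = {
            "scenario": mech.scenario,
            "max_deflection": float(np.abs(state.displacements[:, 2]).max()),
            "load_fraction": state.load_fraction,
        }
        if "analyze" in stages:
            summary["analyze"] = {
                "ratios": [float(r) for r in ratio.ratios],
                "mean_ratio": ratio.mean_ratio,
                "classification": ratio.mean_classification,
            }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return summary
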