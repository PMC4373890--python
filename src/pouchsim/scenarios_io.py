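"""Scenario orchestration, configuration, metrics, outputs and CLI.

Five scenarios are shipped:

* ``homeostasis`` -- healthy tissue, no perturbation;
* ``ulcer``       -- a circular ulcer punched after equilibration, with an
                     inflammatory bolus on the wound bed;
* ``recovery``    -- a window of severe diffuse inflammation, then removal
                     of the stimulus;
* ``knockout``    -- gene knockouts (Wnt, Hh, PTEN, ...) applied after
                     equilibration;
* ``pouchitis``   -- stool fill/empty cycling with accumulating
                     inflammatory potential, driving terminal-dominant
                     metaplasia on an anatomic 3.5 cm x 6 cm pouch
                     (simulated at a desk-scale unit lattice spanning the
                     full axial length).

Every run writes its fully resolved configuration beside its outputs;
(config, seed) fully determines every output byte, and any admissible
worker count produces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import click
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cells as C
from . import signaling as S
from . import stool as ST
from .engine import Simulation
from .geometry import (
    Component,
    CryptVillusUnit,
    GeometryIndex,
    GridCoord,
    PouchGeometry,
    build_pouch,
    lattice_pouch,
    positions_3d,
)

logger = logging.getLogger("pouchsim")

SCENARIOS = ("homeostasis", "ulcer", "recovery", "knockout", "pouchitis")


# ----------------------------------------------------------------------
# configuration

@dataclass
class GeometryConfig:
    """Pouch geometry block.

    ``diameter_cm``/``length_cm`` describe the anatomic cylinder (used
    for size accounting and echoed in the resolved config); the
    simulated lattice is ``sim_n_axial x sim_n_circ`` units.  When
    anatomic dimensions are given, the simulated units are spread over
    the full axial length (each unit standing for a patch of tissue);
    otherwise the template spacing is used directly.
    """

    diameter_cm: Optional[float] = None
    length_cm: Optional[float] = None
    unit_spacing_mm: float = 0.5
    sim_n_axial: int = 8
    sim_n_circ: int = 8
    villus_height: int = 48
    crypt_depth: int = 12
    face_width: int = 6
    n_faces: int = 4
    cap_rows: int = 1
    cell_diameter_um: float = 10.0

    def template(self) -> CryptVillusUnit:
        return CryptVillusUnit(
            villus_height=self.villus_height,
            crypt_depth=self.crypt_depth,
            face_width=self.face_width,
            n_faces=self.n_faces,
            cap_rows=self.cap_rows,
        )

    def build_simulated(self) -> PouchGeometry:
        if self.length_cm is not None:
            spacing = self.length_cm * 10.0 / self.sim_n_axial
        else:
            spacing = self.unit_spacing_mm
        return lattice_pouch(
            self.sim_n_axial, self.sim_n_circ, self.template(), spacing
        )

    def anatomic_echo(self) -> Optional[Dict]:
        """Construct the anatomic cylinder for size accounting."""
        if self.diameter_cm is None or self.length_cm is None:
            return None
        geom = build_pouch(
            self.diameter_cm, self.length_cm, self.unit_spacing_mm,
            self.template(),
        )
        return {
            "diameter_cm": geom.diameter_cm,
            "length_cm": geom.length_cm,
            "unit_spacing_mm": geom.unit_spacing_mm,
            "n_axial": geom.n_axial,
            "n_circ": geom.n_circ,
            "n_units": geom.n_units,
            "total_sites": geom.total_sites(),
        }


@dataclass
class PerturbationConfig:
    """Scenario-specific perturbation timing and magnitudes."""

    ulcer_step: int = 500
    ulcer_radius: int = 6
    ulcer_center_row: Optional[int] = None   # default: mid-villus of center unit
    bolus_tnfa: float = 5.0
    bolus_ros: float = 5.0
    inflammation_start: int = 500
    inflammation_steps: int = 80
    inflammation_ros: float = 0.1
    inflammation_tnfa: float = 0.1
    knockout_step: int = 500
    knockouts: Tuple[str, ...] = ("WNT",)


@dataclass
class ScenarioConfig:
    scenario: str = "homeostasis"
    seed: int = 1
    workers: int = 1
    n_steps: int = 2000
    out_dir: str = "out"
    dump_every: int = 0        # 0: final dump only
    equilibration_steps: int = 500
    stool_enabled: bool = False
    debug: bool = False
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    rules: C.RuleParams = field(default_factory=C.RuleParams)
    signaling: S.SignalingParams = field(default_factory=S.SignalingParams)
    stool: ST.StoolParams = field(default_factory=ST.StoolParams)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)

    # -- (de)serialization; round-trips losslessly through YAML --------

    def to_dict(self) -> Dict:
        d = {
            "scenario": self.scenario,
            "seed": self.seed,
            "workers": self.workers,
            "n_steps": self.n_steps,
            "out_dir": self.out_dir,
            "dump_every": self.dump_every,
            "equilibration_steps": self.equilibration_steps,
            "stool_enabled": self.stool_enabled,
            "debug": self.debug,
            "geometry": asdict(self.geometry),
            "rules": asdict(self.rules),
            "signaling": {
                "fields": {
                    S.MediatorId(m).name: asdict(fp)
                    for m, fp in self.signaling.fields.items()
                },
                "edges": [list(t) for t in self.signaling.network.to_tuples()],
                "w_stat3": self.signaling.w_stat3,
                "crypt_source_rows": self.signaling.crypt_source_rows,
                "villus_source_rows": self.signaling.villus_source_rows,
                "knockouts": list(self.signaling.knockouts),
            },
            "stool": asdict(self.stool),
            "perturbation": asdict(self.perturbation),
        }
        d["perturbation"]["knockouts"] = list(self.perturbation.knockouts)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ScenarioConfig":
        d = dict(d)
        sig_d = d.pop("signaling", None)
        if sig_d is not None:
            sig = S.SignalingParams(
                fields={
                    S.MediatorId[name]: S.FieldParams(**fp)
                    for name, fp in sig_d["fields"].items()
                },
                network=S.SignedNetwork.from_tuples(
                    [tuple(e) for e in sig_d["edges"]]
                ),
                w_stat3=sig_d.get("w_stat3", 0.5),
                crypt_source_rows=sig_d.get("crypt_source_rows", 3),
                villus_source_rows=sig_d.get("villus_source_rows", 4),
                knockouts=tuple(sig_d.get("knockouts", ())),
            )
        else:
            sig = S.SignalingParams()
        pert_d = d.pop("perturbation", {})
        if "knockouts" in pert_d:
            pert_d["knockouts"] = tuple(pert_d["knockouts"])
        geo_d = d.pop("geometry", {})
        rules_d = d.pop("rules", {})
        stool_d = d.pop("stool", {})
        return cls(
            geometry=GeometryConfig(**geo_d),
            rules=C.RuleParams(**rules_d),
            signaling=sig,
            stool=ST.StoolParams(**stool_d),
            perturbation=PerturbationConfig(**pert_d),
            **d,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        self.rules.validate()
        self.signaling.validate()


def shipped_defaults() -> Dict:
    """The documented default parameter file bundled with the package."""
    from importlib import resources

    text = resources.files("pouchsim").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_config(scenario: str, seed: int = 1, **overrides) -> ScenarioConfig:
    """The shipped default configuration of each scenario."""
    cfg = ScenarioConfig(scenario=scenario, seed=seed)
    if scenario == "pouchitis":
        cfg.geometry = GeometryConfig(diameter_cm=3.5, length_cm=6.0)
        cfg.stool_enabled = True
        cfg.stool = ST.StoolParams(delta_ip=0.05)
    elif scenario == "ulcer":
        cfg.n_steps = 1000
    elif scenario == "recovery":
        cfg.n_steps = 1200
    elif scenario == "knockout":
        cfg.n_steps = 1000
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# building and running

def build_simulation(config: ScenarioConfig) -> Simulation:
    """Construct an initialized simulation with scenario perturbations."""
    config.validate()
    geom = config.geometry.build_simulated()
    index = GeometryIndex(geom)
    sim = Simulation(
        index=index,
        rules=config.rules,
        signaling=config.signaling,
        stool_params=config.stool,
        stool_enabled=config.stool_enabled,
        seed=config.seed,
        workers=config.workers,
        debug=config.debug,
    )
    sim.init_tissue()
    pert = config.perturbation
    if config.scenario == "ulcer":
        center = _default_ulcer_center(index, pert)
        sim.at_step(
            pert.ulcer_step,
            lambda s: s.apply_ulcer(
                center, pert.ulcer_radius, pert.bolus_tnfa, pert.bolus_ros
            ),
        )
    elif config.scenario == "recovery":
        def _on(s):
            s.inflam_bolus = (pert.inflammation_ros, pert.inflammation_tnfa)

        def _off(s):
            s.inflam_bolus = (0.0, 0.0)

        sim.at_step(pert.inflammation_start, _on)
        sim.at_step(pert.inflammation_start + pert.inflammation_steps, _off)
    elif config.scenario == "knockout":
        sim.at_step(
            pert.knockout_step,
            lambda s: s.apply_knockouts(pert.knockouts),
        )
    return sim


def _default_ulcer_center(index: GeometryIndex, pert: PerturbationConfig) -> GridCoord:
    geom = index.geom
    u = geom.unit_index(geom.n_axial // 2, geom.n_circ // 2)
    unit = geom.units[u]
    row = (
        pert.ulcer_center_row
        if pert.ulcer_center_row is not None
        else unit.villus_height // 2
    )
    return GridCoord(u, Component.VILLUS, 0, row, unit.face_width // 2)


def run_scenario(config: ScenarioConfig) -> Dict[str, Path]:
    """Run a scenario end to end and write all outputs.

    Phases: init -> equilibration -> perturbation (scenario-specific)
    -> recovery, all inside one ``n_steps`` loop; the perturbation
    schedule comes from the config.  Outputs: resolved_config.yaml,
    timeseries.csv, metrics.json, gradient_profiles.csv, per-site state
    dumps (+ geometry sidecars), a final surface mesh, and for stool
    runs the per-cycle exposure profile; pouchitis adds the axial
    gradient report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    resolved = config.to_dict()
    anatomic = config.geometry.anatomic_echo()
    if anatomic is not None:
        resolved["anatomic_geometry"] = anatomic
        logger.info(
            "anatomic pouch: %d x %d units, %d sites",
            anatomic["n_axial"], anatomic["n_circ"], anatomic["total_sites"],
        )
    paths["resolved_config"] = out / "resolved_config.yaml"
    paths["resolved_config"].write_text(yaml.safe_dump(resolved, sort_keys=True))

    sim = build_simulation(config)
    for step in range(1, config.n_steps + 1):
        sim.step()
        if config.dump_every and step % config.dump_every == 0:
            dump_state(sim, out / f"state_{step:06d}.csv")

    paths["timeseries"] = out / "timeseries.csv"
    sim.series.to_csv(paths["timeseries"], index=False)

    paths["final_state"] = dump_state(sim, out / "state_final.csv")
    paths["mesh"] = out / "tissue_final.ply"
    export_mesh(sim.index, sim.lineage, paths["mesh"],
                cell_diameter_um=config.geometry.cell_diameter_um)

    metrics = compute_metrics(sim, window=_steady_window(config))
    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(json.dumps(metrics.to_dict(), indent=2))

    paths["gradients"] = out / "gradient_profiles.csv"
    S.gradient_profiles_csv(
        sim.conc, sim.index,
        [S.MediatorId.WNT, S.MediatorId.BMP, S.MediatorId.HH],
        paths["gradients"],
    )

    if config.stool_enabled:
        paths["exposure_profile"] = out / "exposure_profile.csv"
        _write_exposure_profile(config, paths["exposure_profile"])
    if config.scenario == "pouchitis":
        report, flags = pouchitis_gradient_report(sim)
        paths["gradient_report"] = out / "pouchitis_gradient_report.csv"
        report.to_csv(paths["gradient_report"], index=False)
        (out / "pouchitis_gradient_flags.json").write_text(
            json.dumps(flags, indent=2)
        )
    paths["simulation"] = sim  # convenience for callers; not a file
    return paths


def _steady_window(config: ScenarioConfig) -> int:
    return max(1, min(500, config.n_steps - config.equilibration_steps))


def _write_exposure_profile(config: ScenarioConfig, path: Path) -> None:
    prof = ST.cycle_exposure_profile(config.geometry.sim_n_axial, config.stool)
    geom = config.geometry.build_simulated()
    axial_mm = np.arange(geom.n_axial) * geom.unit_spacing_mm
    pd.DataFrame(
        {"axial_mm": axial_mm, "cumulative_exposure": prof}
    ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# metrics

@dataclass
class TissueMetrics:
    """Architecture metrics of one tissue state.

    ``villus_crypt_ratio`` is NaN (undefined sentinel, logged) when the
    crypt population is zero.  Heights and metaplastic fractions are
    reported per axial bin; bins cover the pouch axis exactly.
    """

    villus_crypt_ratio: float
    steady_state_ratio: Optional[float]
    axial_bin_edges: List[float]
    mean_villus_height: List[float]
    metaplastic_unit_fraction: List[float]
    population_series: Optional[str] = None

    def to_dict(self) -> Dict:
        d = asdict(self)
        for k in ("villus_crypt_ratio", "steady_state_ratio"):
            if d[k] is not None and not math.isfinite(d[k]):
                d[k] = None
        return d


def compute_metrics(
    sim: Simulation,
    n_bins: int = 10,
    window: Optional[int] = None,
    series_path: Optional[str] = None,
) -> TissueMetrics:
    """Instantaneous architecture metrics plus the steady-state ratio.

    The steady-state ratio averages n_villus/n_crypt over the final
    ``window`` recorded steps (the equilibration window is the caller's
    concern).
    """
    idx = sim.index
    counts = sim.population_counts()
    if counts["n_crypt"] == 0:
        logger.warning("zero crypt population: villus:crypt ratio undefined")
        ratio = math.nan
    else:
        ratio = counts["n_villus"] / counts["n_crypt"]

    steady = None
    if window and len(sim._records) >= window:
        tail = sim.series.tail(window)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = tail["n_villus"].to_numpy() / tail["n_crypt"].to_numpy()
        steady = float(np.nanmean(r))

    geom = idx.geom
    n_bins = min(n_bins, geom.n_axial)
    edges = np.linspace(0, geom.n_axial, n_bins + 1)
    unit_axial = np.arange(geom.n_units) // geom.n_circ
    heights = np.array([u.villus_height for u in geom.units], dtype=float)
    meta = sim.unit_metaplastic.astype(float)
    mean_h, frac = [], []
    for b in range(n_bins):
        m = (unit_axial >= edges[b]) & (unit_axial < edges[b + 1])
        mean_h.append(float(heights[m].mean()))
        frac.append(float(meta[m].mean()))
    return TissueMetrics(
        villus_crypt_ratio=ratio,
        steady_state_ratio=steady,
        axial_bin_edges=[float(e) for e in edges],
        mean_villus_height=mean_h,
        metaplastic_unit_fraction=frac,
        population_series=series_path,
    )


def pouchitis_gradient_report(
    sim: Simulation, n_bins: int = 10
) -> Tuple[pd.DataFrame, Dict]:
    """Axial gradient of villus height and metaplasia after pouchitis.

    Reports per-axial-bin final mean villus height and metaplastic unit
    fraction, and flags (Spearman test over units, alpha = 0.05)
    whether height decreases toward the terminal end.
    """
    geom = sim.index.geom
    metrics = compute_metrics(sim, n_bins=n_bins)
    df = pd.DataFrame(
        {
            "axial_bin": np.arange(len(metrics.mean_villus_height)),
            "axial_start_mm": np.asarray(metrics.axial_bin_edges[:-1])
            * geom.unit_spacing_mm,
            "mean_villus_height": metrics.mean_villus_height,
            "metaplastic_unit_fraction": metrics.metaplastic_unit_fraction,
        }
    )
    unit_axial = np.arange(geom.n_units) // geom.n_circ
    heights = np.array([u.villus_height for u in geom.units], dtype=float)
    if np.ptp(heights) == 0:
        rho, p = math.nan, math.nan
    else:
        rho, p = stats.spearmanr(unit_axial, heights)
    flags = {
        "spearman_rho": None if math.isnan(rho) else float(rho),
        "p_value": None if math.isnan(p) else float(p),
        "monotone_decreasing_toward_terminal": bool(
            not math.isnan(rho) and rho < 0 and p < 0.05
        ),
    }
    return df, flags


def terminal_metaplastic_fraction(sim: Simulation) -> float:
    """Metaplastic unit fraction in the terminal (distal) axial quartile."""
    geom = sim.index.geom
    unit_axial = np.arange(geom.n_units) // geom.n_circ
    cut = geom.n_axial - max(1, geom.n_axial // 4)
    m = unit_axial >= cut
    return float(sim.unit_metaplastic[m].mean())


def make_pouchitis_runner(base: ScenarioConfig):
    """Reduced-scale pouchitis run for delta_IP calibration: returns
    f(delta_ip) -> terminal-quartile metaplastic fraction."""

    def run(delta_ip: float) -> float:
        cfg = replace(
            base,
            stool=replace(base.stool, delta_ip=float(delta_ip)),
            out_dir=base.out_dir,
        )
        sim = build_simulation(cfg)
        sim.run(cfg.n_steps)
        return terminal_metaplastic_fraction(sim)

    return run


# ----------------------------------------------------------------------
# state dumps and meshes

_DUMP_COLUMNS = [
    "site", "unit", "component", "face", "row", "col",
    "lineage", "cycle_clock", "health", "exposure", "cell_id",
]


def dump_state(sim: Simulation, path) -> Path:
    """Per-site state dump (CSV) plus a geometry sidecar (JSON)."""
    idx = sim.index
    df = pd.DataFrame(
        {
            "site": np.arange(idx.n_sites),
            "unit": idx.site_unit,
            "component": idx.site_comp,
            "face": idx.site_face,
            "row": idx.site_row,
            "col": idx.site_col,
            "lineage": sim.lineage,
            "cycle_clock": sim.clock,
            "health": sim.health,
            "exposure": sim.exposure,
            "cell_id": sim.cell_id,
        }
    )
    for m in S.MediatorId:
        df[m.name] = sim.conc[m]
    path = Path(path)
    df.to_csv(path, index=False)
    geom = idx.geom
    sidecar = {
        "diameter_cm": geom.diameter_cm,
        "length_cm": geom.length_cm,
        "unit_spacing_mm": geom.unit_spacing_mm,
        "n_axial": geom.n_axial,
        "n_circ": geom.n_circ,
        "units": [asdict(u) for u in geom.units],
        "unit_metaplastic": sim.unit_metaplastic.astype(int).tolist(),
        "unit_exposure": sim.unit_exposure.tolist(),
        "step": sim.step_count,
    }
    path.with_suffix(".geometry.json").write_text(json.dumps(sidecar))
    return path


def load_dump(path) -> Tuple[pd.DataFrame, GeometryIndex]:
    """Re-read a state dump and rebuild its geometry index."""
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(".geometry.json").read_text())
    geom = PouchGeometry(
        diameter_cm=side["diameter_cm"],
        length_cm=side["length_cm"],
        unit_spacing_mm=side["unit_spacing_mm"],
        n_axial=side["n_axial"],
        n_circ=side["n_circ"],
        units=[CryptVillusUnit(**u) for u in side["units"]],
    )
    return df, GeometryIndex(geom)


LINEAGE_COLORS = {
    int(C.Lineage.STEM): (46, 134, 193),
    int(C.Lineage.PROGENITOR): (244, 208, 63),
    int(C.Lineage.ENTEROCYTE): (88, 214, 141),
    int(C.Lineage.METAPLASTIC): (231, 76, 60),
}


def export_mesh(
    index: GeometryIndex,
    lineage: np.ndarray,
    path,
    units: Optional[Sequence[int]] = None,
    cell_diameter_um: float = 10.0,
) -> Path:
    """Write occupied sites as a colored ASCII PLY point mesh.

    One vertex per occupied site at its 3D embedding, colored by
    lineage; ``units`` optionally restricts the export to a sub-region
    (full anatomic runs are too large to render whole).
    """
    sel = lineage != C.EMPTY
    if units is not None:
        sel &= np.isin(index.site_unit, np.asarray(units))
    pos = positions_3d(index, cell_diameter_um)[sel]
    lin = lineage[sel]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {pos.shape[0]}\n")
        fh.write(
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n"
        )
        for (x, y, z), l in zip(pos, lin):
            r, g, b = LINEAGE_COLORS[int(l)]
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}\n")
    return path


def read_mesh(path) -> Tuple[np.ndarray, np.ndarray]:
    """Parse an ASCII PLY point mesh back to (coords, colors)."""
    lines = Path(path).read_text().splitlines()
    n = 0
    body_at = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            n = int(ln.split()[-1])
        if ln.strip() == "end_header":
            body_at = i + 1
            break
    coords, colors = [], []
    for ln in lines[body_at:body_at + n]:
        parts = ln.split()
        coords.append([float(v) for v in parts[:3]])
        colors.append([int(v) for v in parts[3:6]])
    return (
        np.asarray(coords, dtype=float).reshape(n, 3),
        np.asarray(colors, dtype=int).reshape(n, 3),
    )


# ----------------------------------------------------------------------
# serial/partitioned equivalence

def check_equivalence(
    config: ScenarioConfig,
    worker_counts: Sequence[int] = (1, 2),
    n_steps: Optional[int] = None,
) -> bool:
    """Run the scenario on several worker counts in lockstep and diff the
    full per-site state after every step.  Raises on first divergence."""
    n_steps = n_steps if n_steps is not None else config.n_steps
    sims = [
        build_simulation(replace(config, workers=p)) for p in worker_counts
    ]
    for step in range(1, n_steps + 1):
        refs = None
        for p, sim in zip(worker_counts, sims):
            sim.step()
            sig = sim.state_signature()
            if refs is None:
                refs = sig
            else:
                for name, arr in sig.items():
                    if not np.array_equal(arr, refs[name]):
                        raise AssertionError(
                            f"state divergence at step {step}, field "
                            f"{name!r}, workers {worker_counts[0]} vs {p}"
                        )
    return True


# ----------------------------------------------------------------------
# CLI

@click.group()
def cli() -> None:
    """pouchsim: agent-based ileal-pouch epithelium simulator."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")


@cli.command("run")
@click.option("--scenario", type=click.Choice(SCENARIOS), default=None)
@click.option("--config", "config_file", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--workers", type=int, default=None)
@click.option("--steps", type=int, default=None)
@click.option("--out", "out_dir", type=click.Path(), default=None)
@click.option("--dump-every", type=int, default=None)
@click.option("--check-equivalence", "check_eq", is_flag=True, default=False,
              help="run workers 1 and 2 in lockstep and diff state")
def cli_run(scenario, config_file, seed, workers, steps, out_dir,
            dump_every, check_eq):
    """Run a scenario and write its outputs."""
    check = check_eq
    if config_file:
        cfg = ScenarioConfig.from_yaml(config_file)
        if scenario:
            cfg.scenario = scenario
    else:
        cfg = default_config(scenario or "homeostasis")
    for name, val in (
        ("seed", seed), ("workers", workers), ("n_steps", steps),
        ("out_dir", out_dir), ("dump_every", dump_every),
    ):
        if val is not None:
            setattr(cfg, name, val)
    cfg.validate()
    if check:
        check_equivalence(cfg, (1, 2), n_steps=min(cfg.n_steps, 50))
        click.echo("serial/partitioned equivalence verified (P=1 vs 2)")
    paths = run_scenario(cfg)
    sim = paths.pop("simulation")
    counts = sim.population_counts()
    click.echo(
        f"{cfg.scenario}: {cfg.n_steps} steps, {counts['n_total']} cells "
        f"({counts['n_villus']} villus / {counts['n_crypt']} crypt)"
    )
    for name, p in paths.items():
        click.echo(f"  {name}: {p}")


@cli.command("metrics")
@click.argument("dump", type=click.Path(exists=True))
def cli_metrics(dump):
    """Architecture metrics of a state dump."""
    df, index = load_dump(dump)
    lin = df["lineage"].to_numpy()
    crypt = index.site_comp == int(Component.CRYPT)
    occ = lin != C.EMPTY
    n_crypt = int((occ & crypt).sum())
    n_villus = int((occ & ~crypt).sum())
    ratio = n_villus / n_crypt if n_crypt else None
    click.echo(json.dumps({
        "n_total": int(occ.sum()),
        "n_crypt": n_crypt,
        "n_villus": n_villus,
        "villus_crypt_ratio": ratio,
    }, indent=2))


@cli.command("mesh")
@click.argument("dump", type=click.Path(exists=True))
@click.option("--out", "out_file", type=click.Path(), required=True)
def cli_mesh(dump, out_file):
    """Render a state dump to a colored PLY point mesh."""
    df, index = load_dump(dump)
    export_mesh(index, df["lineage"].to_numpy().astype(np.int8), out_file)
    click.echo(out_file)


if __name__ == "__main__":
    cli()
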