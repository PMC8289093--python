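"""Experiment runner, CSV reference series, and regression comparison.

An :class:`ExperimentSpec` names a model preset from the component
catalog, optional parameter overrides (dotted component-attribute paths,
values with unit strings), solver settings, and a variable filter.
Running it always audits units first, then assembles, simulates, and
writes the filtered trajectory as a deterministic CSV — repeated runs of
the same spec are byte-identical, which is what makes the stored
references usable as regression oracles: any behavioral change of the
code shows up as a diff against the reference data, and the change
summary printed by :func:`update_references` makes it inspectable.

CSV dialect: comma separator, ``.`` decimal, header row, leading column
literally named ``time``, shortest-roundtrip double precision.  A JSON
sidecar (``<name>.meta.json``) records experiment name, kit version and
solver settings.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import (
    ComponentGraph,
    SolverSettings,
    Trajectory,
    simulate,
)
from .presets import MODELS
from .quantities import audit_model_units, quantity

__all__ = [
    "ExperimentSpec",
    "ReferenceSeries",
    "ComparisonReport",
    "Tolerances",
    "ExperimentError",
    "ComparisonError",
    "build_graph",
    "run_experiment",
    "write_csv",
    "read_reference",
    "regression_compare",
    "update_references",
    "DEMO_EXPERIMENTS",
]


class ExperimentError(RuntimeError):
    """A spec failed to resolve, audit, assemble, or simulate."""


class ComparisonError(ValueError):
    """Two series are structurally incomparable (columns / time grids)."""


@dataclass
class ExperimentSpec:
    """A named, fully resolvable experiment configuration."""

    name: str
    model: str
    overrides: dict = field(default_factory=dict)
    settings: SolverSettings = field(default_factory=SolverSettings)
    description: str = ""

    @classmethod
    def from_config(cls, cfg: dict) -> "ExperimentSpec":
        s = cfg.get("settings", {})
        settings = SolverSettings(
            start=float(s.get("start", 0.0)),
            stop=float(s.get("stop", 2.5)),
            tolerance=float(s.get("tolerance", 1e-12)),
            interval=float(s.get("interval", 1e-4)),
            rtol=s.get("rtol"),
            atol=s.get("atol"),
            variable_filter=s.get("variable_filter"),
        )
        return cls(
            name=cfg["name"],
            model=cfg["model"],
            overrides=dict(cfg.get("overrides", {})),
            settings=settings,
            description=cfg.get("description", ""),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentSpec":
        return cls.from_config(yaml.safe_load(Path(path).read_text()))


def _apply_override(graph: ComponentGraph, path: str, value) -> None:
    comp_name, _, attr_path = path.rpartition(".")
    # component names may themselves contain dots: longest-prefix match
    comp = None
    for name in sorted(graph.components, key=len, reverse=True):
        if path == name or path.startswith(name + "."):
            comp = graph.components[name]
            attr_path = path[len(name) + 1 :]
            break
    if comp is None:
        raise ExperimentError(
            f"override {path!r}: no component matches; known components: "
            f"{sorted(graph.components)}"
        )
    parts = attr_path.split(".")
    target = comp
    for part in parts[:-1]:
        if not hasattr(target, part):
            raise ExperimentError(
                f"override {path!r}: {type(target).__name__} has no "
                f"attribute {part!r}"
            )
        target = getattr(target, part)
    leaf = parts[-1]
    if not hasattr(target, leaf):
        raise ExperimentError(
            f"override {path!r}: {type(target).__name__} has no "
            f"attribute {leaf!r}"
        )
    if isinstance(value, dict):
        value = quantity(value["value"], value.get("unit", "1"))
    setattr(target, leaf, value)


def build_graph(spec: ExperimentSpec) -> ComponentGraph:
    """Resolve the spec's model preset and apply its overrides."""
    if spec.model not in MODELS:
        raise ExperimentError(
            f"experiment {spec.name!r}: unknown model {spec.model!r}; "
            f"catalog: {sorted(MODELS)}"
        )
    graph = MODELS[spec.model]()
    for path, value in sorted(spec.overrides.items()):
        _apply_override(graph, path, value)
    return graph


def run_experiment(
    spec: ExperimentSpec, out_dir: str | Path | None = None
) -> tuple[Trajectory, Path | None]:
    """Audit, assemble, simulate; optionally write the CSV + metadata.

    The unit audit runs first and any dimensional inconsistency aborts
    the experiment before a single solver step.
    """
    graph = build_graph(spec)
    graph.assemble()
    verdicts = audit_model_units(graph)
    failures = [v for v in verdicts if not v.passed]
    if failures:
        lines = "\n".join(str(v) for v in failures)
        raise ExperimentError(
            f"experiment {spec.name!r}: unit audit failed:\n{lines}"
        )
    sys = graph.require_assembled()
    traj = simulate(sys, spec.settings)
    path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{spec.name}.csv"
        write_csv(traj, path)
        meta = {
            "experiment": spec.name,
            "kit_version": __version__,
            "model": spec.model,
            "settings": {
                "start": spec.settings.start,
                "stop": spec.settings.stop,
                "tolerance": spec.settings.tolerance,
                "interval": spec.settings.interval,
                "variable_filter": spec.settings.variable_filter,
            },
        }
        (out / f"{spec.name}.meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
    return traj, path


def write_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory with shortest-roundtrip float formatting."""
    lines = [",".join(traj.columns)]
    arr = traj.data.to_numpy()
    for row in arr:
        lines.append(",".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ReferenceSeries:
    """A CSV-backed time series: strictly increasing time + variables."""

    name: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns[0] != "time":
            raise ComparisonError(
                f"{self.name}: first column must be 'time', "
                f"got {self.data.columns[0]!r}"
            )
        t = self.data["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ComparisonError(f"{self.name}: time must strictly increase")

    @classmethod
    def from_trajectory(cls, name: str, traj: Trajectory) -> "ReferenceSeries":
        return cls(name, traj.data)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns[1:])


def read_reference(path: str | Path) -> ReferenceSeries:
    path = Path(path)
    data = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix("").with_suffix(".meta.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return ReferenceSeries(path.stem, data, meta)


@dataclass(frozen=True)
class Tolerances:
    """Per-variable regression tolerance: |a-r| <= abs_floor + rel*|r|."""

    rel: float = 1e-6
    abs_floor: float = 1e-12


@dataclass
class VariableReport:
    variable: str
    max_abs: float
    max_rel: float
    worst_time: float
    passed: bool


@dataclass
class ComparisonReport:
    """Per-variable deviations and the overall regression verdict."""

    variables: list[VariableReport]
    passed: bool

    def failing(self) -> list[VariableReport]:
        return [v for v in self.variables if not v.passed]

    def summary(self) -> str:
        lines = []
        for v in self.variables:
            tag = "ok  " if v.passed else "FAIL"
            lines.append(
                f"{tag} {v.variable}: max|d|={v.max_abs:.3e} "
                f"rel={v.max_rel:.3e} at t={v.worst_time:g}"
            )
        return "\n".join(lines)


def regression_compare(
    actual: ReferenceSeries,
    reference: ReferenceSeries,
    tol: Tolerances = Tolerances(),
    interpolate: bool = False,
) -> ComparisonReport:
    """Compare two series variable by variable on a common time grid.

    Column sets must match exactly (an extra reference column is an
    error, never a silent pass).  Time grids must agree to 1e-12 unless
    ``interpolate=True``, in which case the actual series is linearly
    interpolated onto the reference grid.
    """
    a_cols, r_cols = set(actual.variables), set(reference.variables)
    if a_cols != r_cols:
        missing = sorted(r_cols - a_cols)
        extra = sorted(a_cols - r_cols)
        raise ComparisonError(
            f"column mismatch: missing from actual {missing}, "
            f"unexpected in actual {extra}"
        )
    t_ref = reference.data["time"].to_numpy()
    t_act = actual.data["time"].to_numpy()
    if interpolate:
        get = lambda col: np.interp(
            t_ref, t_act, actual.data[col].to_numpy()
        )
    else:
        if len(t_ref) != len(t_act) or not np.allclose(
            t_ref, t_act, rtol=0, atol=1e-12
        ):
            raise ComparisonError(
                "time grids differ; both series must share the fixed "
                "output interval (or pass interpolate=True)"
            )
        get = lambda col: actual.data[col].to_numpy()
    reports = []
    for col in reference.variables:
        r = reference.data[col].to_numpy()
        a = get(col)
        dev = np.abs(a - r)
        allowed = tol.abs_floor + tol.rel * np.abs(r)
        worst = int(np.argmax(dev - allowed))
        max_abs = float(dev.max()) if len(dev) else 0.0
        denom = np.maximum(np.abs(r), tol.abs_floor)
        max_rel = float((dev / denom).max()) if len(dev) else 0.0
        reports.append(
            VariableReport(
                variable=col,
                max_abs=max_abs,
                max_rel=max_rel,
                worst_time=float(t_ref[worst]) if len(t_ref) else 0.0,
                passed=bool(np.all(dev <= allowed)),
            )
        )
    return ComparisonReport(reports, all(v.passed for v in reports))


def update_references(
    specs: Iterable[ExperimentSpec],
    ref_dir: str | Path,
    tol: Tolerances = Tolerances(),
) -> list[str]:
    """Re-run experiments and atomically replace their reference CSVs.

    All experiments are run first; if any fails, no reference is touched.
    Returns (and prints) a change summary listing exactly the experiments
    whose output differs from the stored reference.
    """
    ref_dir = Path(ref_dir)
    ref_dir.mkdir(parents=True, exist_ok=True)
    results: list[tuple[ExperimentSpec, Trajectory]] = []
    for spec in specs:
        traj, _ = run_experiment(spec)  # raises on failure, refs untouched
        results.append((spec, traj))
    changed: list[str] = []
    for spec, traj in results:
        target = ref_dir / f"{spec.name}.csv"
        status = "new"
        if target.exists():
            old = read_reference(target)
            new = ReferenceSeries.from_trajectory(spec.name, traj)
            try:
                report = regression_compare(new, old, tol)
                status = "unchanged" if report.passed else "changed"
            except ComparisonError:
                status = "changed"
        if status != "unchanged":
            changed.append(f"{spec.name}: {status}")
        with tempfile.NamedTemporaryFile(
            "w", dir=ref_dir, suffix=".tmp", delete=False
        ) as tmp:
            tmp_path = Path(tmp.name)
        write_csv(traj, tmp_path)
        os.replace(tmp_path, target)
        meta = {
            "experiment": spec.name,
            "kit_version": __version__,
            "model": spec.model,
        }
        (ref_dir / f"{spec.name}.meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
    for line in changed:
        print(line)
    return changed


#: Shipped demo experiments.  Horizons and tolerances are sized for
#: routine regression use on a single CPU.
DEMO_EXPERIMENTS: list[ExperimentSpec] = [
    ExperimentSpec(
        name="gate_relaxation",
        model="gate_relaxation",
        settings=SolverSettings(
            start=0.0, stop=0.2, tolerance=1e-10, interval=1e-3
        ),
        description="single HH gate relaxing under a constant clamp",
    ),
    ExperimentSpec(
        name="ist_step",
        model="ist_voltage_clamp",
        settings=SolverSettings(
            start=0.0, stop=0.5, tolerance=1e-10, interval=1e-3
        ),
        description="sustained-inward channel under a holding clamp",
    ),
    ExperimentSpec(
        name="calcium_dummy",
        model="calcium_dummy",
        settings=SolverSettings(
            start=0.0,
            stop=0.3,
            tolerance=1e-10,
            interval=1e-3,
            atol=1e-28,
            variable_filter=r"ca\.(sub|cyto|jsr|nsr)\.c",
        ),
        description="calcium handling driven by dummy Gaussian currents",
    ),
    ExperimentSpec(
        name="demo_cell_pulse",
        model="demo_cell_an",
        settings=SolverSettings(
            start=0.0,
            stop=0.9,
            tolerance=1e-8,
            interval=1e-3,
            atol=1e-28,
            variable_filter=r"cell\.cm\.v|cell\.ca\.(sub|cyto)\.c",
        ),
        description="reduced demo cell under the current-pulse protocol",
    ),
]
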