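"""Experiment runner, deterministic CSV output, regression comparison."""

import numpy as np
import pandas as pd
import pytest

from avnode.experiments import (
    DEMO_EXPERIMENTS,
    ComparisonError,
    ExperimentError,
    ExperimentSpec,
    ReferenceSeries,
    Tolerances,
    read_reference,
    regression_compare,
    run_experiment,
    update_references,
    write_csv,
)
from avnode.network import SolverSettings


def _spec(name="gate_relaxation", **kw):
    base = dict(
        name=name,
        model="gate_relaxation",
        settings=SolverSettings(
            start=0.0, stop=0.05, tolerance=1e-10, interval=1e-3
        ),
    )
    base.update(kw)
    return ExperimentSpec(**base)


class TestRunExperiment:
    def test_writes_csv_with_filtered_columns(self, tmp_path):
        spec = _spec(
            settings=SolverSettings(
                start=0.0,
                stop=0.05,
                tolerance=1e-10,
                interval=1e-3,
                variable_filter=r"ch\.(gate\.n|i)",
            )
        )
        traj, path = run_experiment(spec, out_dir=tmp_path)
        assert traj.columns == ["time", "ch.gate.n", "ch.i"]
        assert path.exists()
        header = path.read_text().splitlines()[0]
        assert header == "time,ch.gate.n,ch.i"

    def test_unknown_model_named_in_error(self):
        spec = _spec(model="no_such_model")
        with pytest.raises(ExperimentError) as err:
            run_experiment(spec)
        assert "no_such_model" in str(err.value)

    def test_unknown_override_named_in_error(self):
        spec = _spec(overrides={"ghost.g_max": 1.0})
        with pytest.raises(ExperimentError) as err:
            run_experiment(spec)
        assert "ghost.g_max" in str(err.value)

    def test_override_changes_trajectory(self):
        base, _ = run_experiment(_spec())
        halved, _ = run_experiment(
            _spec(
                overrides={
                    "vc.drive": {"value": -40.0, "unit": "mV"},
                }
            )
        )
        assert not np.allclose(base["ch.gate.n"], halved["ch.gate.n"])

    def test_unit_audit_gates_the_run(self):
        from avnode.quantities import quantity

        spec = _spec(
            overrides={"ch.channel.g_max": quantity(1.0, "V")}
        )
        with pytest.raises(ExperimentError) as err:
            run_experiment(spec)
        assert "unit audit" in str(err.value)

    def test_repeated_runs_are_bit_identical(self, tmp_path):
        spec = _spec()
        _, p1 = run_experiment(spec, out_dir=tmp_path / "a")
        _, p2 = run_experiment(spec, out_dir=tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()


class TestCSVRoundTrip:
    def test_write_read_write_is_byte_identical(self, tmp_path):
        traj, path = run_experiment(_spec(), out_dir=tmp_path)
        ref = read_reference(path)
        path2 = tmp_path / "again.csv"
        write_csv(
            __import__("avnode.network", fromlist=["Trajectory"]).Trajectory(
                ref.data
            ),
            path2,
        )
        assert path.read_bytes() == path2.read_bytes()

    def test_metadata_sidecar_written(self, tmp_path):
        _, path = run_experiment(_spec(), out_dir=tmp_path)
        meta = path.with_suffix("").with_suffix(".meta.json")
        assert meta.exists()
        assert "kit_version" in meta.read_text()


class TestRegressionCompare:
    def _series(self, **cols):
        t = np.linspace(0.0, 1.0, 11)
        data = pd.DataFrame({"time": t, **cols})
        return ReferenceSeries("s", data)

    def test_identical_series_pass_with_zero_deviation(self):
        a = self._series(x=np.linspace(0, 1, 11))
        b = self._series(x=np.linspace(0, 1, 11))
        report = regression_compare(a, b)
        assert report.passed
        assert report.variables[0].max_abs == 0.0

    def test_perturbation_fails_naming_variable_and_time(self):
        tol = Tolerances(rel=1e-6, abs_floor=1e-12)
        x = np.linspace(0, 1, 11)
        y = x.copy()
        y[7] += 10 * (tol.abs_floor + tol.rel * abs(x[7]))
        report = regression_compare(self._series(x=y), self._series(x=x), tol)
        assert not report.passed
        failing = report.failing()
        assert failing[0].variable == "x"
        assert failing[0].worst_time == pytest.approx(0.7)

    def test_extra_reference_column_is_an_error(self):
        a = self._series(x=np.zeros(11))
        b = self._series(x=np.zeros(11), extra=np.ones(11))
        with pytest.raises(ComparisonError) as err:
            regression_compare(a, b)
        assert "extra" in str(err.value)

    def test_mismatched_time_grids_rejected_without_interpolation(self):
        a = self._series(x=np.zeros(11))
        t2 = np.linspace(0.0, 1.0, 21)
        b = ReferenceSeries("s", pd.DataFrame({"time": t2, "x": np.zeros(21)}))
        with pytest.raises(ComparisonError):
            regression_compare(a, b)
        report = regression_compare(a, b, interpolate=True)
        assert report.passed

    def test_reflexive_for_every_shipped_experiment_output(self, tmp_path):
        for spec in DEMO_EXPERIMENTS[:2]:
            _, path = run_experiment(spec, out_dir=tmp_path)
            ref = read_reference(path)
            assert regression_compare(ref, ref).passed


class TestUpdateReferences:
    def test_first_run_populates_empty_directory(self, tmp_path):
        changed = update_references([_spec()], tmp_path / "refs")
        assert changed == ["gate_relaxation: new"]
        assert (tmp_path / "refs" / "gate_relaxation.csv").exists()

    def test_unchanged_model_leaves_references_byte_identical(self, tmp_path):
        ref_dir = tmp_path / "refs"
        update_references([_spec()], ref_dir)
        before = (ref_dir / "gate_relaxation.csv").read_bytes()
        changed = update_references([_spec()], ref_dir)
        assert changed == []
        assert (ref_dir / "gate_relaxation.csv").read_bytes() == before

    def test_parameter_change_listed_in_summary(self, tmp_path):
        ref_dir = tmp_path / "refs"
        update_references([_spec()], ref_dir)
        modified = _spec(
            overrides={"vc.drive": {"value": -40.0, "unit": "mV"}}
        )
        changed = update_references([modified], ref_dir)
        assert changed == ["gate_relaxation: changed"]

    def test_failing_experiment_touches_nothing(self, tmp_path):
        ref_dir = tmp_path / "refs"
        update_references([_spec()], ref_dir)
        before = (ref_dir / "gate_relaxation.csv").read_bytes()
        bad = _spec(name="bad", model="no_such_model")
        with pytest.raises(ExperimentError):
            update_references([_spec(), bad], ref_dir)
        assert (ref_dir / "gate_relaxation.csv").read_bytes() == before
        assert not (ref_dir / "bad.csv").exists()


class TestConfigLoading:
    def test_spec_from_yaml_file(self, tmp_path):
        cfg = tmp_path / "exp.yaml"
        cfg.write_text(
            "name: custom\n"
            "model: gate_relaxation\n"
            "settings:\n"
            "  stop: 0.02\n"
            "  tolerance: 1.0e-9\n"
            "  interval: 1.0e-3\n"
            "  variable_filter: 'ch\\.gate\\.n'\n"
        )
        spec = ExperimentSpec.from_file(cfg)
        traj, _ = run_experiment(spec)
        assert traj.columns == ["time", "ch.gate.n"]
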