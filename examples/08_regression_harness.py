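"""The regression harness: run, store references, compare.

Runs a shipped demo experiment twice (byte-identical output), stores the
CSV as reference data, then perturbs a parameter and shows the comparison
catching the change.
"""

import tempfile
from pathlib import Path

from avnode.experiments import (
    ExperimentSpec,
    Tolerances,
    read_reference,
    regression_compare,
    run_experiment,
    update_references,
)
from avnode.network import SolverSettings

work = Path(tempfile.mkdtemp())
spec = ExperimentSpec(
    name="gate_relaxation",
    model="gate_relaxation",
    settings=SolverSettings(stop=0.05, tolerance=1e-10, interval=1e-3),
)

_, p1 = run_experiment(spec, out_dir=work / "run1")
_, p2 = run_experiment(spec, out_dir=work / "run2")
print("two runs byte-identical:", p1.read_bytes() == p2.read_bytes())

update_references([spec], work / "refs")
ref = read_reference(work / "refs" / "gate_relaxation.csv")

# identical comparison is reflexive
print("self-comparison passes:", regression_compare(ref, ref).passed)

# perturb the clamp level and compare against the stored reference
perturbed = ExperimentSpec(
    name="gate_relaxation",
    model="gate_relaxation",
    overrides={"vc.drive": {"value": -21.0, "unit": "mV"}},
    settings=spec.settings,
)
traj, _ = run_experiment(perturbed)
from avnode.experiments import ReferenceSeries

report = regression_compare(
    ReferenceSeries.from_trajectory("gate_relaxation", traj),
    ref,
    Tolerances(rel=1e-6, abs_floor=1e-12),
)
print("\nafter shifting the clamp by 1 mV:")
print(report.summary())
print("overall verdict:", "pass" if report.passed else "FAIL (as expected)")
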