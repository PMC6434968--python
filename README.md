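# cordstim

Simulator of intradural (subdural) spinal cord stimulation: anisotropic
volume-conductor fields of a 12-site T-shaped electrode array placed inside
the dural sac over an idealized thoracic cord segment, coupled to
myelinated-axon activation models, with montage steering sweeps, power
accounting and electrode charge-safety analysis.

## What it computes

* **Fields** — the quasi-static potential `div(sigma grad V) = 0` on a
  nonuniform voxel mesh of the layered cord (gray matter, anisotropic white
  matter, CSF, dura/extradural shell), with electrode sites modeled as
  perfect-conductor supernodes carrying prescribed total currents. Twelve
  unit-current basis fields and the mutual-resistance matrix make any
  montage a cheap superposition; power is the quadratic form `I^T R I`.
* **Activation** — 21-node myelinated axons (three diameter classes:
  7.3, 11.5, 15 um) driven through the extracellular potential along their
  nodes; a fiber is recruited when any node crosses +5 mV during/after a
  200 us cathodic pulse. A numba batch integrator scans a 0.1 mm grid over
  the cord cross-section and classifies each point by which classes fire.
* **Steering** — depth and lateral montage schedules with per-trial
  amplitude calibration against the zero-gray-matter-activation constraint,
  reporting recruited areas, recruitment depth, power and per-site charge
  safety (50 uC/cm^2 electrode limit, 30 uC/cm^2 tissue limit).

## Quick start (library)

```python
import numpy as np
from cordstim import (ExperimentConfig, Montage, build_model, superpose,
                      make_depth_schedule, run_sweep)

model = build_model(ExperimentConfig())        # mesh + 12 basis fields (~1 min)

cur = np.zeros(12); cur[[2, 3]] = -2.0; cur[[0, 5]] = 2.0   # mA
sol = superpose(model.basis, Montage(cur))
print(sol.power_mW, sol.site_voltages)

sched = make_depth_schedule(model.layout)
sweep = run_sweep(model.basis, sched, model.grid, model.geometry)
for t in sweep.trials:
    print(t.name, t.amplitude_mA, t.power_mW, t.total_activated_area_mm2)
```

Smaller, faster examples live in `examples/` (they use a coarsened mesh and
run in seconds to a couple of minutes each).

## Quick start (CLI)

```bash
cordstim mesh --vtk mesh.vtk              # build + inspect the voxel mesh
cordstim basis --out basis.npz            # solve the 12 basis fields
cordstim field  --basis-file basis.npz -- "0.5 0 -0.5 -0.5 0 0.5 0 0 0 0 0 0"
cordstim map    --basis-file basis.npz -- "2 0 -2 -2 0 2 0 0 0 0 0 0"
cordstim sweep depth --basis-file basis.npz --out sweep.json
cordstim safety -- "-4.3 0 0 0 0 0 2.15 2.15 0 0 0 0"
cordstim report --seed 1 --out report.json   # summary study figures (slow)
```

Note the `--` before current lists that start with a minus sign.

## Tests

```bash
python -m pytest -q
```

The suite includes unit and property tests per module plus
`tests/test_acceptance.py` with one test per acceptance criterion; the full
run solves the default-resolution model once and takes ~10-15 minutes.

See `docs/methods.md` for the numerical methods, model assumptions and unit
conventions.
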