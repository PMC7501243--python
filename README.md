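# fmtkit

Analysis toolkit for **flow magnetic tweezers (FMT)** — the high-throughput
single-molecule geometry in which DNA tethers are stretched by combined
magnetic (vertical) and flow (lateral drag) forces, so that tether-length
changes appear as lateral bead displacements in very large fields of view.
The package is for experimentalists processing tens of thousands of tethered
beads per experiment: it tracks beads, calibrates force per molecule,
segments traces, and classifies topoisomerase (gyrase) activity
automatically.

## What it does

- **Tracking** (`fmtkit.tracking`): discoidal filtering, threshold +
  local-maximum detection, subpixel 2-D Gaussian localization, KD-tree
  radius-search linking, stuck-bead drift correction, and the localization
  precision formula
  `sigma = sqrt(s²/N + a²/(12N) + 8π s⁴ b²/(a² N²))`.
- **Force calibration** (`fmtkit.calibration`): the equipartition /
  worm-like-chain system — `F = k_B T l / ⟨δy²⟩` solved jointly with
  `F P/(k_B T) = ¼(1−l/l0)⁻² − ¼ + l/l0` — with motion-blur correction
  `S(α) = 2/α − 2/α²(1−e^{−α})`, `α = F W/(l·6πηR)`, plus tether geometry
  and channel drag.
- **Change points** (`fmtkit.changepoint`): exhaustive two-line SSE
  segmentation with F-test gating, for buckling transitions and burst
  segment tables.
- **Classification** (`fmtkit.classify`): the automated pipeline — mobility
  and attachment from flow reversal, coilability and tether multiplicity
  from high-force coiling, per-molecule force, nm-per-turn calibration,
  sliding-window gyrase bursts in cycles/s (each enzymatic cycle changes
  linking number by −2), α/χ tagging, DNA-break statistics with bootstrap
  errors, IC50 dose–response fits, treadmilling cycle counts.
- **Simulation** (`fmtkit.simulate`): ground-truth generator for all of the
  above — Ornstein–Uhlenbeck bead fluctuations with camera blur,
  extension-vs-turns hat curves with force-dependent buckling asymmetry,
  full protocol traces with gyrase kinetics and rare tether breaks, labeled
  cohorts, rendered TIFF stacks.
- **Archives** (`fmtkit.archive`): UUID-keyed molecule records (trajectory,
  parameters, tags, segment tables, processing log) in a JSON container
  with an offset index, so single records load from multi-gigabyte files
  without parsing the rest.

## Worked example

Simulate a labeled cohort, classify it, and read off gyrase kinetics:

```python
import numpy as np
from fmtkit import CohortSpec, simulate_cohort, classify_archive, default_timeline

tl = default_timeline()
arch, truth = simulate_cohort(CohortSpec(n_molecules=200, seed=42), tl)
results, bursts = classify_archive(arch, tl)

df = results.merge(truth, on="uid", suffixes=("", "_true"))
singles = df[df["accepted"]]
print(f"accepted {len(singles)}/{len(df)} molecules")
print(f"median force      {singles['force_pN'].median():.3f} pN")
print(f"median v_pos      {singles['v_pos'].median():.2f} cycles/s")
print(f"median v_neg      {singles['v_neg'].median():.2f} cycles/s")
```

Output:

```
accepted 98/200 molecules
median force      0.200 pN
median v_pos      1.27 cycles/s
median v_neg      0.66 cycles/s
```

The cohort contains 50 % single tethers (the rest stuck, nicked or
multiply-tethered, which the pipeline rejects); the recovered median force
matches the injected 0.2 pN median, and the burst velocities recover the
injected 1.26 / 0.65 cycles/s — positive-supercoil relaxation and negative-
supercoil introduction — to within a few percent.

The same workflow runs from the shell:

```bash
fmtkit simulate --config cfg.yaml --seed 42 --out run/
fmtkit analyze --config cfg.yaml --archive run/archive.json \
               --timeline run/timeline.yaml --out run/
```

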