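# atriflow

Desk-scale, moving-domain CFD analysis of the left atrium (LA) for
stroke-risk biomarkers. The package generates synthetic moving-chamber
"patients" (tagged tetrahedral mesh + frame-wise wall displacements),
turns the frames into a smooth volumetric mesh motion (periodic smoothing
splines + stiffened harmonic lifting), solves the incompressible
Navier–Stokes equations in ALE form (stabilized P1–P1, implicit Euler),
computes functional and hemodynamic biomarkers (volumes/SV/EF, E/A waves,
ostium area, appendage tortuosity; flow stasis, TAWSS, OSI, RRT, ECAP,
kinetic energy, enstrophy, phase-gated vorticity), and merges them with a
penalized logistic separation analysis of stroke vs control phenotypes.

Everything runs on one CPU at coarse "desk" resolutions; all file formats
are plain text (ASCII VTU, JSON, CSV, YAML).

## Layout

| module | role |
| --- | --- |
| `atriflow.cohort` | phenotype sampling, chamber mesh generator, volume waveform, frame displacements |
| `atriflow.motion` | periodic smoothing splines, wall distance, stiffened harmonic lifting, ALE velocity |
| `atriflow.flow` | stabilized ALE Navier–Stokes solver, valve schedule, flowrates |
| `atriflow.functional` | enclosed volume, SV/EF, E/A analysis, LAA centerline + tortuosity, ostium area |
| `atriflow.features` | phase averaging, flow stasis, WSS-derived wall features, energy/enstrophy, region medians |
| `atriflow.risk` | cohort table, penalized logistic separation, separation matrix, ratio normalization |
| `atriflow.io`, `atriflow.pipeline`, `atriflow.cli` | VTU/JSON plumbing, orchestration, command line |
| `atriflow.fixtures`, `atriflow.benchmarks` | analytic meshes (box/tube/icosphere) and solver benchmarks |

## CLI

```bash
# generate a synthetic cohort (meshes + frames + metadata)
atriflow generate --n-control 4 --n-stroke 4 --seed 1 --out out/cohort --edge-length 0.005

# run CFD + features on one generated case
atriflow simulate --case out/cohort/C1 --dt 5e-3 --beats 3 --out out/C1_run

# full pipeline: cohort -> motion -> CFD -> features -> separation matrices
atriflow run-all --n-control 4 --n-stroke 4 --seed 1 --edge-length 0.005 --out out/run

# recompute separation matrices from a cohort CSV / print a report
atriflow merge --table out/run/cohort.csv --out out/matrices
atriflow report --out out/run
```

Units: SI internally (m, s, Pa); volumes are reported in mL, areas in
mm², pressures configured in mmHg.

## Notes on scale

Defaults are desk-scale: 4–5 mm edge length (≈2–8k tets), `dt` = 2–5 ms,
2–3 beats. Publication-scale settings (0.8 mm mesh, `dt` = 0.5 ms, 10
beats, phase average over 8 beats after discarding 2) are plain config
options but are not runnable in minutes on one CPU.
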