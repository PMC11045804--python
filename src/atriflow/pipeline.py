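"""End-to-end orchestration: cohort -> motion -> CFD -> features -> merge.

A :class:`RunConfig` collects every stage's parameters (defaults match
the per-module design defaults); :func:`run_pipeline` executes all cases,
isolating per-case failures, and emits the cohort table plus the
separation matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _fem
from .cohort import (
    ML, GeometryParams, PhenotypeParams, build_reference_mesh, sample_cohort,
    scale_to_volume, volume_waveform, frames_from_waveform,
)
from .errors import AtriflowError
from .features import (
    flow_stasis, global_traces, phase_average, region_medians,
    vorticity_phase_medians, wall_features, wss_history,
)
from .flow import (
    MMHG, BoundarySpec, FluidProperties, SolverConfig, mv_schedule, run,
    section_flowrate, _outward_flux,
)
from .functional import (
    VolumeTrace, ea_peak_times, functional_summary, smooth_trace_spline,
)
from .motion import LiftingConfig, fit_displacement_model, volumetric_motion
from .risk import assemble_cohort_table, correlation_matrix

log = logging.getLogger("atriflow")

__all__ = ["RunConfig", "CaseManifest", "run_case", "run_pipeline"]


@dataclass
class RunConfig:
    # cohort
    n_control: int = 4
    n_stroke: int = 4
    seed: int = 1
    # geometry
    edge_length: float = 0.004
    # motion
    smoothing_weight: float | str = 0.0
    lifting_alpha: float = 1.5e-3
    lifting_beta: float = 2.0
    # solver
    dt: float = 2e-3
    n_beats: int = 3
    output_stride: int = 2
    refactor_every: int = 8
    p_in_mmHg: float = 10.0
    p_out_mmHg: float = 5.0
    backflow_coefficient: float = 1.0
    density: float = 1.06e3
    dynamic_viscosity: float = 3.5e-3
    # features
    n_discard: int = 1
    n_average: int | None = None
    fs_threshold: float = 0.1
    # output
    out_dir: str | None = None
    write_frames: bool = False

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CaseManifest:
    case_id: str
    files: dict = field(default_factory=dict)  # name -> path
    hashes: dict = field(default_factory=dict)  # name -> sha256

    def add(self, name, path):
        p = Path(path)
        self.files[name] = str(p)
        self.hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def validate(self):
        for name, path in self.files.items():
            p = Path(path)
            if not p.exists():
                raise AtriflowError(f"manifest file missing: {path}")
            if hashlib.sha256(p.read_bytes()).hexdigest() != self.hashes[name]:
                raise AtriflowError(f"manifest hash mismatch: {path}")


def _case_id(p: PhenotypeParams, index: int) -> str:
    return f"{'C' if p.group == 'control' else 'S'}{index + 1}"


def build_case_geometry(p: PhenotypeParams, config: RunConfig):
    """Per-case chamber: axes and appendage scale with volume, inlets stay
    fixed, and the outlet radius scales with sqrt(stroke volume).

    The outlet scaling ties the pressure-driven transmitral (conduit) flow
    to the phenotype's transport capacity, mirroring the reduced valve
    flowrates of low-stroke-volume cases; fixed inlets keep the disks
    resolvable at desk-scale mesh sizes.
    """
    base = GeometryParams()
    s = (p.v_max / 78.0) ** (1.0 / 3.0)
    r_mv = base.mv_radius * min(1.25, max(0.7, np.sqrt(p.stroke_volume / 40.0)))
    gp = GeometryParams(
        chamber_semi_axes=tuple(a * s for a in base.chamber_semi_axes),
        pv_radius=base.pv_radius,
        mv_radius=r_mv,
        laa_length=base.laa_length * s,
        laa_radius=base.laa_radius * s,
        laa_bend_angle=base.laa_bend_angle,
        target_edge_length=config.edge_length,
    )
    return scale_to_volume(build_reference_mesh(gp), p.v_max)


def run_case(p: PhenotypeParams, config: RunConfig, case_id: str = "case",
             case_dir: Path | None = None) -> dict:
    """Full single-case pipeline; returns the cohort-table row."""
    t_start = time.time()
    geom = build_case_geometry(p, config)
    trace = volume_waveform(p)
    frames = frames_from_waveform(geom, trace, p)
    model = fit_displacement_model(frames, config.smoothing_weight)
    lift_cfg = LiftingConfig(alpha=config.lifting_alpha, beta=config.lifting_beta)
    motion = volumetric_motion(geom, model, lift_cfg)

    sched = mv_schedule(trace, period=p.period)
    bc = BoundarySpec(
        p_in=config.p_in_mmHg * MMHG, p_out=config.p_out_mmHg * MMHG,
        mv_schedule=sched, period=p.period,
        backflow_coefficient=config.backflow_coefficient,
    )
    fluid = FluidProperties(density=config.density,
                            dynamic_viscosity=config.dynamic_viscosity)
    scfg = SolverConfig(dt=config.dt, n_beats=config.n_beats,
                        output_stride=config.output_stride,
                        refactor_every=config.refactor_every)
    history = run(geom, motion, fluid, bc, scfg)
    log.info("case %s: CFD done (%d snaps, beat-diffs %s, %.1fs)",
             case_id, len(history.times),
             [f"{d:.3f}" for d in history.beat_l2_differences],
             time.time() - t_start)

    n_discard = min(config.n_discard, config.n_beats - 1)
    pa = phase_average(history, n_discard, config.n_average)
    fs = flow_stasis(pa, config.fs_threshold)
    wall_ids, wss = wss_history(pa, geom, mu=fluid.dynamic_viscosity)
    wf = wall_features(wss, wall_ids)
    gt = global_traces(pa, geom)

    # phase-averaged MV flowrate and the valve phases
    from .cohort import TAG_MV
    q_pa = np.empty(len(pa.times))
    for k, t in enumerate(pa.times):
        pts = geom.vertices + pa.d[k]
        if bc.mv_open(t):
            q_pa[k] = _outward_flux(pts, geom.facets_of(TAG_MV), pa.u[k],
                                    motion.velocity(t)) / ML
        else:
            q_pa[k] = 0.0
    t_open = next(t for t, s in sched if s == "open")
    t_close = next(t for t, s in sched if s == "closed")
    open_iv = (t_open, t_close if t_close > t_open else t_close + p.period)
    sys_time = ((t_close + (t_open + p.period)) / 2) % p.period

    vort_med = None
    e_t = a_t = None
    try:
        e_t, a_t = ea_peak_times(pa.times, q_pa, open_iv)
        vort_med = vorticity_phase_medians(pa, geom, e_t, a_t, sys_time)
    except AtriflowError as exc:
        log.warning("case %s: wave detection failed (%s)", case_id, exc)
    med = region_medians(geom, fs, wf, vort_med)

    d_min = motion.displacement(t_close)
    summary = functional_summary(
        p, trace, geom=geom, q_mv=q_pa, q_times=pa.times,
        open_interval=open_iv, min_volume_displacement=d_min,
    )

    # appendage stroke volume from the tagged cells
    laa_row = {}
    if len(geom.laa_cells):
        def laa_vol(disp):
            pts = geom.vertices + disp
            return float(np.abs(_fem.tet_volumes(pts, geom.tetrahedra)[geom.laa_cells]).sum()) / ML

        v0 = laa_vol(motion.displacement(t_open))
        v1 = laa_vol(d_min)
        laa_row = {"laa_v_max": max(v0, v1), "laa_v_min": min(v0, v1),
                   "laa_sv": abs(v0 - v1)}

    row = {"case_id": case_id, "group": p.group}
    row.update({k: v for k, v in asdict(summary).items()})
    row.update(laa_row)
    for m in med:
        prefix = m.region.lower()
        row[f"{prefix}_fs"] = m.fs
        row[f"{prefix}_tawss"] = m.tawss
        row[f"{prefix}_osi"] = m.osi
        row[f"{prefix}_rrt"] = m.rrt
        row[f"{prefix}_ecap"] = m.ecap
        if m.vort_e is not None:
            row[f"{prefix}_vort_e"] = m.vort_e
            row[f"{prefix}_vort_a"] = m.vort_a
            row[f"{prefix}_vort_sys"] = m.vort_sys

    if case_dir is not None:
        case_dir = Path(case_dir)
        case_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_case
        write_case(case_dir, geom, frames=frames if config.write_frames else None,
                   phenotype=p)
        traces = pd.DataFrame({
            "time_s": history.times, "V_mL": history.volume_mL,
            "Q_MV_mL_s": history.q_mv_mL_s, "Q_PV_total_mL_s": history.q_pv_mL_s,
            "Ek": history.kinetic_energy,
        })
        traces.to_csv(case_dir / "traces.csv", index=False)
        pd.DataFrame({
            "time_s": gt.times, "Ek_phase_avg": gt.kinetic_energy,
            "enstrophy": gt.enstrophy,
        }).to_csv(case_dir / "global_traces.csv", index=False)
    log.info("case %s: done in %.1fs", case_id, time.time() - t_start)
    return row


def run_pipeline(config: RunConfig):
    """Run the whole cohort; returns (manifests, table, matrices, errors).

    Per-case failures are logged as machine-readable records and do not
    abort the remaining cases.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "run_config.yaml")

    cohort = sample_cohort(config.n_control, config.n_stroke, config.seed)
    counters = {"control": 0, "stroke": 0}
    rows, manifests, errors = [], [], []
    for p in cohort:
        cid = _case_id(p, counters[p.group])
        counters[p.group] += 1
        case_dir = out_dir / cid if out_dir else None
        try:
            rows.append(run_case(p, config, case_id=cid, case_dir=case_dir))
            if case_dir:
                man = CaseManifest(case_id=cid)
                for f in sorted(case_dir.glob("*")):
                    man.add(f.name, f)
                manifests.append(man)
        except (AtriflowError, ValueError) as exc:
            rec = {"case_id": cid, "stage": "pipeline", "error": type(exc).__name__,
                   "message": str(exc)}
            errors.append(rec)
            log.error("case %s failed: %s", cid, json.dumps(rec))

    table = assemble_cohort_table(rows)
    matrices = {}
    if len(table) and table["group"].nunique() == 2:
        for region in ("LA", "LAA"):
            try:
                matrices[region] = correlation_matrix(table, region=region)
            except (AtriflowError, ValueError) as exc:
                log.error("matrix %s failed: %s", region, exc)
    if out_dir:
        table.to_csv(out_dir / "cohort.csv", index=False)
        for region, m in matrices.items():
            m.to_csv(out_dir / f"separation_matrix_{region.lower()}.csv")
        (out_dir / "errors.json").write_text(json.dumps(errors, indent=1))
    return manifests, table, matrices, errors
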