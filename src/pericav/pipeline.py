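"""Pipeline driver: paired cavity/no-cavity simulations and the report.

For each impulsive load case the same mesh pair is simulated twice - once
with the cavity as ALE fluid coupled through the penalty interface (the
"TH" configuration) and once with the cavity filled by parenchyma (the
"NTH" configuration) - and the regional injury metrics are compared with
the no-cavity model as reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from pericav import metrics as dm
from pericav import stats as ps
from pericav.coupling import (WallCoupling, default_penalty_stiffness,
                              wall_penalization,
                              pressure_traction_forces)
from pericav.fluid import FluidGrid, fluid_step
from pericav.geometry import (GeometryParams, QuadMesh, build_paired_geometry,
                              HIPPOCAMPAL_SUBFIELDS, PERICAVITY_ROIS,
                              DISTAL_CONTROL, MAT_FLUID, MAT_SUBSTITUTE)
from pericav.loading import LoadCase, generate_load_case, IMPACT_CASES, GRAVITY
from pericav.materials import (EOSParams, SolidMaterialParams, ViscousParams)
from pericav.solid import (SolidSolver, stable_timestep,
                           characteristic_lengths)

__all__ = ["SolverSettings", "RunConfig", "SimulationResult",
           "PairedCaseResult", "ExperimentResult", "run_single_model",
           "run_paired_experiment", "mechanism_report", "demo_config",
           "full_config"]

HIPPOCAMPUS = "hippocampus"


@dataclass
class SolverSettings:
    """Numerical settings of the coupled explicit run."""

    cfl_factor: float = 0.5
    fluid_cfl: float = 0.4
    output_interval: float = 1e-4        # s, metric sampling period
    end_time: float = 0.015              # s, pulse + ring-down
    # with the moving-wall boundary sealing the interface against
    # advection, the penalty only corrects residual wall/interface
    # separation; bulk-scale stiffness would amplify the contour's
    # sub-cell quantization noise into forces that crush the soft tissue
    penalty_relaxation: float = 1e-4
    penalty_damping_factor: float = 0.02  # x rho0*C, interface dashpot
    penalty_traction_cap: float = 2e4     # Pa, bound on interface tractions
    traction_smoothing_time: float = 2e-5  # s, EMA on wall pressure
    solid_bulk_viscosity: float = 0.15    # linear bulk-viscosity coefficient
    solid_shear_viscosity: float = 0.03   # Pa·s, damps element-scale modes
    halo_cells: int = 4                  # void-mesh margin around the cavity
    coupling_stride: int = 1             # fluid substeps per coupling update


@dataclass
class RunConfig:
    """Complete, serializable description of a paired experiment."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    material: SolidMaterialParams = field(default_factory=SolidMaterialParams)
    eos: EOSParams = field(default_factory=EOSParams)
    viscous: ViscousParams = field(default_factory=ViscousParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    cases: tuple = tuple(IMPACT_CASES)   # dicts: label, peaks, severity
    pulse_duration: float = 0.010        # s
    pulse_shape: str = "haversine"
    pulse_direction: float = 0.0         # rad, in-plane
    output_dir: str | None = None
    seed: int = 0

    def load_cases(self) -> list[LoadCase]:
        out = []
        for case in self.cases:
            out.append(generate_load_case(
                peak_translation=case["peak_translation_g"] * GRAVITY,
                peak_rotation=case["peak_rotation_krad_s2"] * 1e3,
                duration=self.pulse_duration, shape=self.pulse_shape,
                direction=self.pulse_direction,
                label=case["label"], severity=case.get("severity", ""),
                metadata=dict(case)))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cases"] = [dict(c) for c in self.cases]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("geometry", GeometryParams),
                         ("material", SolidMaterialParams),
                         ("eos", EOSParams), ("viscous", ViscousParams),
                         ("solver", SolverSettings)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "geometry" and "roi_band_spec" in sub:
                    sub["roi_band_spec"] = tuple(sub["roi_band_spec"] or ())
                d[key] = typ(**sub)
        if "cases" in d:
            d["cases"] = tuple(dict(c) for c in d["cases"])
        return cls(**d)


def demo_config() -> RunConfig:
    """Single-case demonstration at the default desk scale.

    The simulated window equals the impact pulse; the injury metrics are
    peaks over the loading, which occur within it.
    """
    return RunConfig(cases=(IMPACT_CASES[0],),
                     solver=SolverSettings(end_time=0.010))


def full_config() -> RunConfig:
    """All six impact cases (minutes of compute per case)."""
    return RunConfig(solver=SolverSettings(end_time=0.010))


# ---------------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Outcome of one model (TH or NTH) under one load case."""

    model: str                       # "TH" | "NTH"
    case: str
    peaks: dm.ElementPeaks
    labels: np.ndarray               # per active element
    roi_summaries: dict              # roi -> ROISummary
    cavity_max_shear: float          # Pa: fluid (TH) or substitute (NTH)
    load_hash: str
    diagnostics: dict


def _cavity_indicator(p: GeometryParams):
    r_lo = p.cavity_center_radius - p.cavity_thickness / 2
    r_hi = p.cavity_center_radius + p.cavity_thickness / 2
    th0 = p.cavity_theta_center - p.cavity_theta_extent / 2

    def indicator(x, y):
        r = np.hypot(x, y)
        rel = (np.arctan2(y, x) - th0) % (2 * np.pi)
        return (r_lo < r) & (r < r_hi) & (rel < p.cavity_theta_extent)

    return indicator


def _build_fluid_grid(p: GeometryParams, cfg: RunConfig) -> FluidGrid:
    """Cartesian grid covering the cavity plus the void-mesh halo."""
    r_lo = p.cavity_center_radius - p.cavity_thickness / 2
    r_hi = p.cavity_center_radius + p.cavity_thickness / 2
    th0 = p.cavity_theta_center - p.cavity_theta_extent / 2
    th1 = p.cavity_theta_center + p.cavity_theta_extent / 2
    ths = np.linspace(th0, th1, 65)
    pts = np.concatenate([
        np.column_stack([r_lo * np.cos(ths), r_lo * np.sin(ths)]),
        np.column_stack([r_hi * np.cos(ths), r_hi * np.sin(ths)])])
    dx = p.cavity_thickness / p.cavity_layers
    halo = cfg.solver.halo_cells * dx
    x0 = pts[:, 0].min() - halo
    y0 = pts[:, 1].min() - halo
    nx = int(np.ceil((pts[:, 0].max() + halo - x0) / dx))
    ny = int(np.ceil((pts[:, 1].max() + halo - y0) / dx))
    return FluidGrid.from_indicator(_cavity_indicator(p), x0, y0, dx, nx, ny,
                                    eos=cfg.eos)


def _load_hash(load: LoadCase) -> str:
    h = hashlib.sha256()
    for arr in (load.times, load.a_x, load.a_y, load.alpha_z):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def run_single_model(mesh: QuadMesh, load: LoadCase, config: RunConfig,
                     model: str, progress: bool = False) -> SimulationResult:
    """Simulate one model under one load case and summarize its metrics."""
    cfg = config
    solver = SolidSolver(mesh, cfg.material, exclude_fluid=True,
                         rotation_center=(0.0, 0.0),
                         bulk_viscosity=cfg.solver.solid_bulk_viscosity,
                         shear_viscosity=cfg.solver.solid_shear_viscosity)
    has_fluid = bool(np.any(mesh.element_material == MAT_FLUID))

    grid = coupler = None
    n_sub = 0
    dt = stable_timestep(mesh, cfg.material, cfg.solver.cfl_factor,
                         active=solver.active)
    if has_fluid:
        grid = _build_fluid_grid(cfg.geometry, cfg)
        k_pen = default_penalty_stiffness(grid, cfg.solver.penalty_relaxation)
        c_damp = (cfg.solver.penalty_damping_factor
                  * cfg.eos.rho0 * cfg.eos.C)
        coupler = WallCoupling(mesh.boundary_sets["cavity_wall"], k_pen,
                               damping=c_damp,
                               traction_cap=cfg.solver.penalty_traction_cap,
                               deadband_cells=0.5)
        coupler.calibrate(mesh.node_coordinates, grid)
        # keep the penalty spring stable under the solid step
        wall_nodes = np.unique(coupler.wall_edges)
        m_min = solver.mass[wall_nodes].min()
        seg = np.diff(mesh.node_coordinates[coupler.wall_edges], axis=1)
        l_max = np.hypot(seg[..., 0], seg[..., 1]).max()
        dt_pen = 0.5 * 2.0 / math.sqrt(k_pen * l_max / m_min)
        dt = min(dt, dt_pen)
        dt_fl = cfg.solver.fluid_cfl * grid.dx / grid.eos.C
        n_sub = max(1, int(np.ceil(dt / dt_fl)))

    # fictitious-force geometry (reference positions; deformations are small
    # relative to the domain, so the frame terms use the reference frame)
    X = mesh.node_coordinates
    rx, ry = X[:, 0], X[:, 1]
    omega_tab = np.concatenate(
        [[0.0], np.cumsum(0.5 * (load.alpha_z[1:] + load.alpha_z[:-1])
                          * np.diff(load.times))])
    if has_fluid:
        xs = grid.x0 + np.arange(grid.nx + 1)[:, None] * grid.dx
        yxc = grid.y0 + (np.arange(grid.ny)[None, :] + 0.5) * grid.dx
        fgx = np.broadcast_to(xs, (grid.nx + 1, grid.ny))
        fgy = np.broadcast_to(yxc, (grid.nx + 1, grid.ny))
        xc = grid.x0 + (np.arange(grid.nx)[:, None] + 0.5) * grid.dx
        yv = grid.y0 + np.arange(grid.ny + 1)[None, :] * grid.dx
        fvx = np.broadcast_to(xc, (grid.nx, grid.ny + 1))
        fvy = np.broadcast_to(yv, (grid.nx, grid.ny + 1))

    def frame_terms(t):
        at_x = np.interp(t, load.times, load.a_x, left=0.0, right=0.0)
        at_y = np.interp(t, load.times, load.a_y, left=0.0, right=0.0)
        al = np.interp(t, load.times, load.alpha_z, left=0.0, right=0.0)
        om = np.interp(t, load.times, omega_tab,
                       left=0.0, right=omega_tab[-1])
        return at_x, at_y, al, om * om

    labels = mesh.element_region[solver.active].astype(str)
    peaks = dm.ElementPeaks.zeros(solver.conn.shape[0], solver.areas)
    substitute = (mesh.element_material[solver.active] == MAT_SUBSTITUTE)
    cavity_shear = 0.0
    energy_log = []
    mass0 = grid.total_mass() if has_fluid else 0.0

    # explicit stability is tracked on the deformed mesh: compressing
    # elements shrink their own stable step, so dt adapts downward (with a
    # floor) and recovers afterwards
    dt0 = dt
    c_dil = math.sqrt((cfg.material.K + 4.0 * cfg.material.G0 / 3.0)
                      / cfg.material.density)
    dt_fl = (cfg.solver.fluid_cfl * grid.dx / grid.eos.C
             if has_fluid else None)
    next_record = cfg.solver.output_interval
    body = np.empty_like(solver.u)
    p_smooth = np.zeros((grid.nx, grid.ny)) if has_fluid else None
    ext_smooth = np.zeros_like(solver.u)
    fstep = 0
    k = 0
    n_steps_total = 0
    while solver.t < cfg.solver.end_time:
        if k % 25 == 0 and k > 0:
            h_min = characteristic_lengths(
                mesh, solver.active, X + solver.u).min()
            dt = min(dt0, max(cfg.solver.cfl_factor * h_min / c_dil,
                              dt0 / 16.0))
            if has_fluid:
                n_sub = max(1, int(np.ceil(dt / dt_fl)))
        t = solver.t
        at_x, at_y, al, om2 = frame_terms(t)
        body[:, 0] = -at_x + al * ry + om2 * rx
        body[:, 1] = -at_y - al * rx + om2 * ry

        ext = None
        if has_fluid:
            pos = X + solver.u
            # the wall is a moving container boundary for the fluid; the
            # contour penalty corrects residual wall/interface separation
            wall = mesh.boundary_sets["cavity_wall"]
            grid.set_penalization(*wall_penalization(
                grid, pos, wall, solver.v))
            f_solid, ffx, ffy, _ = coupler.forces(pos, grid,
                                                  node_velocities=solver.v)
            dt_f = dt / n_sub
            gax = -at_x + al * fgy + om2 * fgx
            gay = -at_y - al * fvx + om2 * fvy
            p_avg = np.zeros((grid.nx, grid.ny))
            for s in range(n_sub):
                if s > 0 and s % cfg.solver.coupling_stride == 0:
                    _, ffx, ffy, _ = coupler.forces(
                        pos, grid, node_velocities=solver.v)
                fluid_step(grid, dt_f, fstep, force_x=ffx, force_y=ffy,
                           accel_x=gax, accel_y=gay)
                fstep += 1
                p_avg += grid.pressure()
            p_avg /= n_sub
            # wall traction from time-smoothed pressure: the tissue on the
            # other side of the interface is impedance-matched to CSF, so
            # the wall responds to the mean load, not to the cavity's
            # internal acoustic ringing (which the stiff closed box would
            # otherwise reflect and re-radiate)
            if cfg.solver.traction_smoothing_time > 0:
                alpha = min(dt / cfg.solver.traction_smoothing_time, 1.0)
                p_smooth = (1 - alpha) * p_smooth + alpha * p_avg
            else:
                p_smooth = p_avg
            ext = f_solid + pressure_traction_forces(
                grid, pos, wall, cfg.solver.penalty_traction_cap,
                pressure=p_smooth)
            # the same low-pass keeps sub-cell interface chatter (contour
            # and dashpot noise) out of the tissue
            if cfg.solver.traction_smoothing_time > 0:
                alpha = min(dt / cfg.solver.traction_smoothing_time, 1.0)
                ext_smooth = (1 - alpha) * ext_smooth + alpha * ext
                ext = ext_smooth
            cavity_shear = max(cavity_shear, grid.max_shear_stress())

        solver.step(dt, body_accel=body, external_forces=ext)
        k += 1
        n_steps_total += 1

        if solver.t >= next_record - 0.5 * dt or solver.t >= cfg.solver.end_time:
            next_record += cfg.solver.output_interval
            f = solver.element_fields()
            strain = dm.green_lagrange_principal(f.F)
            rate = dm.rate_of_deformation_principal(f.L)
            shear = dm.max_shear_stress(f.stress)
            peaks.update(strain, rate, shear)
            if substitute.any():
                cavity_shear = max(cavity_shear,
                                   float(shear[substitute].max()))
            ke, se = solver.energies()
            energy_log.append((solver.t, ke, se))
            if progress:
                print(f"  [{model}] t={solver.t*1e3:6.2f} ms  "
                      f"KE={ke:9.3e}  SE={se:9.3e}")

    rois = [r for r in np.unique(labels) if r]
    summaries = dm.summarize_rois(peaks, labels, rois)
    union = np.where(np.isin(labels, HIPPOCAMPAL_SUBFIELDS),
                     HIPPOCAMPUS, labels)
    if (union == HIPPOCAMPUS).sum() >= 2:
        summaries[HIPPOCAMPUS] = dm.summarize_rois(
            peaks, union, [HIPPOCAMPUS])[HIPPOCAMPUS]

    diagnostics = {
        "dt": dt0, "n_steps": n_steps_total, "fluid_substeps": n_sub,
        "energy_log": np.array(energy_log),
        "fluid_mass_drift": (abs(grid.total_mass() / mass0 - 1.0)
                             if has_fluid and mass0 > 0 else 0.0),
        "max_penetration": coupler.max_abs_penetration if coupler else 0.0,
    }
    return SimulationResult(model=model, case=load.label, peaks=peaks,
                            labels=labels, roi_summaries=summaries,
                            cavity_max_shear=cavity_shear,
                            load_hash=_load_hash(load),
                            diagnostics=diagnostics)


# ---------------------------------------------------------------------------
@dataclass
class PairedCaseResult:
    case: str
    th: SimulationResult
    nth: SimulationResult

    def percent_difference(self, roi: str, metric: str) -> float:
        th = getattr(self.th.roi_summaries[roi], metric)
        nth = getattr(self.nth.roi_summaries[roi], metric)
        return ps.percent_difference(th, nth)


@dataclass
class ExperimentResult:
    config: RunConfig
    cases: list                      # list[PairedCaseResult]
    comparisons: dict                # metric -> list[PairedComparison]

    def roi_table(self, metric: str, model: str) -> dict:
        """{roi: [per-case value]} for one metric and model."""
        out: dict[str, list] = {}
        for pc in self.cases:
            sim = pc.th if model == "TH" else pc.nth
            for roi, summ in sim.roi_summaries.items():
                out.setdefault(roi, []).append(getattr(summ, metric))
        return out


def run_paired_experiment(config: RunConfig,
                          progress: bool = False) -> ExperimentResult:
    """Run both models across all configured load cases and compare."""
    th_mesh, nth_mesh = build_paired_geometry(config.geometry)
    results = []
    for load in config.load_cases():
        if progress:
            print(f"case {load.label}")
        th = run_single_model(th_mesh, load, config, "TH", progress)
        nth = run_single_model(nth_mesh, load, config, "NTH", progress)
        if th.load_hash != nth.load_hash:
            raise RuntimeError("paired models saw different load inputs")
        results.append(PairedCaseResult(load.label, th, nth))

    exp = ExperimentResult(config, results, {})
    if len(results) >= 4:
        for metric in ("strain_p95", "rate_p95"):
            th_tab = exp.roi_table(metric, "TH")
            nth_tab = exp.roi_table(metric, "NTH")
            common = {r: v for r, v in th_tab.items()
                      if r in nth_tab and len(v) == len(results)}
            exp.comparisons[metric] = ps.compare_rois(
                common, nth_tab, metric)
    if config.output_dir:
        _write_outputs(exp, config.output_dir)
    return exp


def mechanism_report(exp: ExperimentResult, distal_tol: float = 5.0) -> str:
    """Human-readable report: per-ROI TH/NTH values, percent differences,
    signed-rank statistics, and the distal-control consistency flag."""
    if not exp.cases:
        raise ValueError("no completed paired cases to report")
    lines = []
    lines.append("Paired cavity (TH) vs cavity-substitute (NTH) comparison")
    lines.append("=" * 72)
    for metric, name, unit in (("strain_p95", "strain", "-"),
                               ("rate_p95", "strain rate", "1/s")):
        lines.append(f"\n95th-percentile peak {name} [{unit}]")
        lines.append(f"{'ROI':<16}{'case':<10}{'TH':>12}{'NTH':>12}{'diff %':>9}")
        for pc in exp.cases:
            for roi in sorted(pc.th.roi_summaries):
                if roi not in pc.nth.roi_summaries:
                    raise ValueError(f"missing NTH summary for ROI {roi!r}")
                tv = getattr(pc.th.roi_summaries[roi], metric)
                nv = getattr(pc.nth.roi_summaries[roi], metric)
                pd = ps.percent_difference(tv, nv) if nv else float("nan")
                lines.append(f"{roi:<16}{pc.case:<10}{tv:>12.4g}"
                             f"{nv:>12.4g}{pd:>9.1f}")
    for metric, comps in exp.comparisons.items():
        lines.append(f"\nSigned-rank test across cases ({metric}):")
        lines.append(f"{'ROI':<16}{'median (Q1, Q3) %':>28}{'W+':>6}{'p':>8}")
        for c in sorted(comps, key=lambda c: c.roi):
            lines.append(f"{c.roi:<16}"
                         f"{c.median:>10.1f} ({c.q1:.1f}, {c.q3:.1f})"
                         f"{c.W_plus:>8.1f}{c.p:>8.3f}")
    lines.append("\nCavity shear stress (max over run):")
    for pc in exp.cases:
        lines.append(f"  {pc.case}: fluid cavity {pc.th.cavity_max_shear:.3g}"
                     f" Pa | solid substitute {pc.nth.cavity_max_shear:.3g} Pa")
    lines.append("\nDistal control check (strain |percent difference| "
                 f"< {distal_tol:.0f}%):")
    for pc in exp.cases:
        if DISTAL_CONTROL in pc.th.roi_summaries:
            ref = pc.nth.roi_summaries[DISTAL_CONTROL]
            if ref.strain_p95 == 0 or ref.rate_p95 == 0:
                lines.append(f"  {pc.case}: undeformed (zero reference)")
                continue
            pd_s = pc.percent_difference(DISTAL_CONTROL, "strain_p95")
            pd_r = pc.percent_difference(DISTAL_CONTROL, "rate_p95")
            flag = " OK" if abs(pd_s) < distal_tol else " EXCEEDED"
            lines.append(f"  {pc.case}: strain {pd_s:+.2f}%{flag}  "
                         f"(rate {pd_r:+.2f}%, reverberation-limited in 2D)")
    return "\n".join(lines)


def _write_outputs(exp: ExperimentResult, outdir: str) -> None:
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for pc in exp.cases:
        for sim in (pc.th, pc.nth):
            for roi, s in sim.roi_summaries.items():
                for metric in ("strain_p95", "rate_p95",
                               "exceed_strain_frac", "exceed_rate_frac"):
                    rows.append({"case": pc.case, "model": sim.model,
                                 "roi": roi, "metric": metric,
                                 "value": getattr(s, metric)})
            rows.append({"case": pc.case, "model": sim.model,
                         "roi": "cavity", "metric": "max_shear_stress",
                         "value": sim.cavity_max_shear})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "roi_summaries.csv"),
                              index=False)
    srows = []
    for metric, comps in exp.comparisons.items():
        for c in comps:
            srows.append({"metric": metric, "roi": c.roi,
                          "median_pct": c.median, "q1_pct": c.q1,
                          "q3_pct": c.q3, "W_plus": c.W_plus,
                          "z": c.z, "p": c.p})
    if srows:
        pd.DataFrame(srows).to_csv(
            os.path.join(outdir, "paired_stats.csv"), index=False)
    drows = []
    for pc in exp.cases:
        for sim in (pc.th, pc.nth):
            log = sim.diagnostics.get("energy_log")
            if log is None or not len(log):
                continue
            for t, ke, se in log:
                drows.append({"case": pc.case, "model": sim.model,
                              "time": t, "kinetic_energy": ke,
                              "strain_energy": se,
                              "fluid_mass_drift":
                                  sim.diagnostics["fluid_mass_drift"],
                              "max_penetration":
                                  sim.diagnostics["max_penetration"]})
    if drows:
        pd.DataFrame(drows).to_csv(
            os.path.join(outdir, "diagnostics.csv"), index=False)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(exp.config.to_dict(), fh, indent=2, default=str)
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(mechanism_report(exp))
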