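"""End-to-end study pipeline.

Stages: generate a corresponded synthetic cohort -> fit the PCA shape model
-> SD-sweep augmentation -> centerline morphometrics -> representative
selection -> healthy simulations (template-calibrated Windkessels) -> ECMO
subset selection (largest LCCA mean-flow deviation) -> shock/ECMO
simulations at EF levels -> report tables. Every stage writes its artifacts
under the output directory and the run manifest records a SHA-256 per file,
so a fixed seed reproduces the run hash-for-hash.

Interface units are mmHg and L/min; SI is used internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hemodynamics as hd
from . import morphometry as mm
from . import population as pop
from . import ssm

__all__ = ["PipelineConfig", "RunManifest", "run_all", "report", "STAGES"]

STAGES = ("generate", "ssm", "morpho", "select", "healthy", "ecmo", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Reproducible configuration of the full study."""

    seed: int = 0
    out_dir: str = "aortaflow_run"
    n_subjects: int = 19
    bovine_arch_probability: float = 0.2
    resolution: pop.Resolution = field(default_factory=pop.Resolution)
    n_modes: int | None = None  # None -> n_subjects (fixed-size mode book)
    k_select: int = 20
    mode_limit: int = 10
    ecmo_subset_size: int = 4
    include_template_in_ecmo: bool = True
    ef_levels_lmin: tuple[float, ...] = (0.0, 4.0, 6.0)
    shock_reduction: float = 0.70
    healthy_mean_lmin: float = 5.0
    period: float = 0.8
    systole_fraction: float = 0.35
    dt: float = 1e-3
    n_cycles: int = 3
    fluid: hd.FluidProps = field(default_factory=hd.FluidProps)
    targets: hd.CalibrationTargets = field(default_factory=hd.CalibrationTargets)
    smooth_window: int = 5
    write_meshes: bool = False
    write_timeseries: bool = True

    def validate(self) -> None:
        if any(ef < 0 for ef in self.ef_levels_lmin):
            raise ValueError("EF levels must be non-negative")
        if not (0 <= self.shock_reduction < 1):
            raise ValueError("shock_reduction must lie in [0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Counter-based per-stage seed fan-out (stage-level reproducibility)."""
        return (self.seed * 1009 + STAGES.index(stage)) % (2**31)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_jsonable(dataclasses.asdict(self))))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "resolution" in raw:
            raw["resolution"] = pop.Resolution(**raw["resolution"])
        if "fluid" in raw:
            raw["fluid"] = hd.FluidProps(**raw["fluid"])
        if "targets" in raw:
            t = raw["targets"]
            if "peak_pressure_band_mmhg" in t:
                t["peak_pressure_band_mmhg"] = tuple(t["peak_pressure_band_mmhg"])
            raw["targets"] = hd.CalibrationTargets(**t)
        if "ef_levels_lmin" in raw:
            raw["ef_levels_lmin"] = tuple(raw["ef_levels_lmin"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config echo, seeds, file hashes."""

    package_version: str
    seed: int
    config: dict
    stage_seeds: dict
    files: dict = field(default_factory=dict)  # relative path -> sha256
    timestamps: dict = field(default_factory=dict)  # stage -> ISO time
    selected_healthy: list = field(default_factory=list)
    selected_ecmo: list = field(default_factory=list)

    def record(self, out_dir: Path, path: Path) -> None:
        rel = str(path.relative_to(out_dir))
        self.files[rel] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, out_dir: Path) -> Path:
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_generate(cfg: PipelineConfig, out: Path, man: RunManifest):
    spec = pop.PopulationSpec(
        n_subjects=cfg.n_subjects,
        bovine_arch_probability=cfg.bovine_arch_probability,
        seed=cfg.stage_seed("generate"),
    )
    geoms = pop.sample_population(spec, cfg.resolution)
    d = out / "population"
    manifest = pop.write_population(
        geoms, d, spec=spec,
        mesh_format="ply" if cfg.write_meshes else None,
        centerlines=False,
    )
    for p in sorted(d.iterdir()):
        man.record(out, p)
    man.timestamps["generate"] = _now()
    return spec, geoms


def _stage_ssm(cfg: PipelineConfig, spec, geoms, out: Path, man: RunManifest):
    n_modes = cfg.n_modes if cfg.n_modes is not None else cfg.n_subjects
    # canonical mean-anatomy layout (non-bovine) for all SSM-generated shapes
    layout = pop.build_geometry(
        dataclasses.replace(spec.means, bovine_arch=False), cfg.resolution).layout
    model = ssm.fit_pca(geoms, n_modes=n_modes, layout=layout)
    d = out / "model"
    ssm.save_model(model, d)
    augmented = ssm.augment_dataset(model)
    (d / "augmented_labels.json").write_text(
        json.dumps([g.label for g in augmented], indent=2))
    for p in sorted(d.iterdir()):
        man.record(out, p)
    man.timestamps["ssm"] = _now()
    return model, augmented


def _stage_morpho(cfg: PipelineConfig, augmented, out: Path, man: RunManifest):
    tractsets = {
        g.label: mm.split_tracts(g.centerline_tree) for g in augmented
    }
    table = mm.feature_table(tractsets, smooth_window=cfg.smooth_window)
    table = mm.compare_to_template(table)
    d = out / "morphometry"
    d.mkdir(parents=True, exist_ok=True)
    table.to_csv(d / "features.csv", index=False)
    summary = mm.population_summary(table)
    summary.to_csv(d / "population_summary.csv")
    # result planes of the template
    planes = mm.define_result_planes(tractsets["template"])
    (d / "result_planes.json").write_text(json.dumps([
        {"name": p.name, "origin_mm": p.origin.tolist(), "normal": p.normal.tolist()}
        for p in planes
    ], indent=2))
    for p in sorted(d.iterdir()):
        man.record(out, p)
    man.timestamps["morpho"] = _now()
    return table


def _stage_select(cfg: PipelineConfig, table, out: Path, man: RunManifest):
    labels = mm.select_representatives(table, k=cfg.k_select, mode_limit=cfg.mode_limit)
    d = out / "selection"
    d.mkdir(parents=True, exist_ok=True)
    (d / "healthy_selection.json").write_text(json.dumps(labels, indent=2))
    man.record(out, d / "healthy_selection.json")
    man.selected_healthy = labels
    man.timestamps["select"] = _now()
    return labels


def _network_for(geometry, cfg: PipelineConfig, with_ecmo_return: bool):
    tracts = mm.split_tracts(geometry.centerline_tree)
    return hd.build_network(tracts, cfg.fluid, with_ecmo_return=with_ecmo_return)


def _write_timeseries(res: hd.SimulationResult, path: Path) -> None:
    cols = {"time_s": res.t}
    for j, name in enumerate(res.junction_names):
        cols[f"P_{name}_mmhg"] = res.P_junction[:, j] / hd.MMHG
    for name, q in res.outlet_flows.items():
        cols[f"Q_{name}_lmin"] = q / hd.LMIN
    pd.DataFrame(cols).to_csv(path, index=False)


def _stage_healthy(cfg: PipelineConfig, model, augmented, labels, out: Path,
                   man: RunManifest):
    by_label = {g.label: g for g in augmented}
    waveform = hd.default_cardiac_waveform(
        mean_lmin=cfg.healthy_mean_lmin, period=cfg.period,
        systole_fraction=cfg.systole_fraction)
    sim_cfg = hd.SimulationConfig(dt=cfg.dt, n_cycles=cfg.n_cycles, mode="healthy")

    template_net = _network_for(by_label["template"], cfg, with_ecmo_return=False)
    wk = hd.calibrate_rcr(template_net, waveform, cfg.targets, sim_cfg)

    d = out / "healthy"
    d.mkdir(parents=True, exist_ok=True)
    (d / "windkessels.json").write_text(json.dumps({
        name: {"Rp": p.Rp, "Rd": p.Rd, "C": p.C, "P0": p.P0, "tau": p.tau}
        for name, p in wk.items()
    }, indent=2))

    run_labels = list(labels) if "template" in labels else list(labels) + ["template"]
    rows = []
    for label in run_labels:
        net = _network_for(by_label[label], cfg, with_ecmo_return=False)
        net.windkessels = dict(wk)
        res = hd.simulate(net, waveform, sim_cfg)
        means = res.mean_outlet_flows_lmin()
        rows.append({"label": label, "peak_root_pressure_mmhg": res.peak_root_pressure_mmhg(),
                     **{f"Qmean_{k}_lmin": v for k, v in means.items()}})
        if cfg.write_timeseries:
            _write_timeseries(res, d / f"timeseries_{label}.csv")
    flows = pd.DataFrame(rows).set_index("label").sort_index()
    flows.to_csv(d / "healthy_flows.csv")
    for p in sorted(d.iterdir()):
        man.record(out, p)
    man.timestamps["healthy"] = _now()
    return wk, flows


def _stage_ecmo(cfg: PipelineConfig, model, augmented, wk, healthy_flows, out: Path,
                man: RunManifest):
    by_label = {g.label: g for g in augmented}
    # subset: largest |LCCA cycle-mean deviation from template| in healthy runs
    tmpl_lcca = healthy_flows.loc["template", "Qmean_LCCA_lmin"]
    dev = (healthy_flows["Qmean_LCCA_lmin"] - tmpl_lcca).abs().drop("template")
    subset = list(dev.sort_values(ascending=False, kind="stable")
                  .index[: cfg.ecmo_subset_size])
    man.selected_ecmo = subset
    run_labels = (["template"] if cfg.include_template_in_ecmo else []) + subset

    healthy_wave = hd.default_cardiac_waveform(
        mean_lmin=cfg.healthy_mean_lmin, period=cfg.period,
        systole_fraction=cfg.systole_fraction)
    shock_wave = hd.scale_waveform(healthy_wave, reduction=cfg.shock_reduction)

    d = out / "ecmo"
    d.mkdir(parents=True, exist_ok=True)
    (d / "ecmo_selection.json").write_text(json.dumps(subset, indent=2))

    flow_rows, ws_rows = [], []
    for label in run_labels:
        net = _network_for(by_label[label], cfg, with_ecmo_return=True)
        net.windkessels = dict(wk)
        for ef in cfg.ef_levels_lmin:
            sim_cfg = hd.SimulationConfig(dt=cfg.dt, n_cycles=cfg.n_cycles,
                                          ef_lmin=ef, mode="shock")
            res = hd.simulate(net, shock_wave, sim_cfg)
            hd.transport_fraction(res, net)
            means = res.mean_outlet_flows_lmin()
            frac = hd.branch_fraction(res, net)
            flow_rows.append({
                "label": label, "ef_lmin": ef,
                "peak_root_pressure_mmhg": res.peak_root_pressure_mmhg(),
                **{f"Qmean_{k}_lmin": v for k, v in means.items()},
                **{f"phi_{k}": v for k, v in frac.items()},
            })
            for phase in ("systolic", "diastolic"):
                ws = hd.watershed_location(res, net, phase)
                ws_rows.append({"label": label, "ef_lmin": ef, "phase": phase,
                                "zone": ws.zone, "s_star_mm": ws.s_star / 1e-3,
                                "multiple_sign_changes": ws.multiple_sign_changes})
            if cfg.write_timeseries:
                _write_timeseries(res, d / f"timeseries_{label}_ef{ef:g}.csv")
    pd.DataFrame(flow_rows).to_csv(d / "ecmo_flows.csv", index=False)
    pd.DataFrame(ws_rows).to_csv(d / "watershed.csv", index=False)
    for p in sorted(d.iterdir()):
        man.record(out, p)
    man.timestamps["ecmo"] = _now()


def _stage_report(out: Path, man: RunManifest | None = None):
    d = out / "report"
    d.mkdir(parents=True, exist_ok=True)
    healthy = pd.read_csv(out / "healthy" / "healthy_flows.csv", index_col="label")
    if not (out / "ecmo" / "ecmo_flows.csv").exists():
        raise FileNotFoundError("ecmo stage outputs missing; run the 'ecmo' stage first")
    ecmo = pd.read_csv(out / "ecmo" / "ecmo_flows.csv")
    ws = pd.read_csv(out / "ecmo" / "watershed.csv")

    # per-outlet healthy mean-flow percent deviation from the template
    qcols = [c for c in healthy.columns if c.startswith("Qmean_")]
    pct = 100.0 * (healthy[qcols] - healthy.loc["template", qcols]) \
        / healthy.loc["template", qcols]
    pct.columns = [c.replace("Qmean_", "pct_").replace("_lmin", "") for c in qcols]
    pct.to_csv(d / "healthy_flow_deviation_pct.csv")

    # mean flow vs EF: linear fit per (geometry, branch)
    fit_rows = []
    for label, grp in ecmo.groupby("label"):
        for branch in ("BCA", "LCCA", "LSA"):
            x = grp["ef_lmin"].to_numpy()
            y = grp[f"Qmean_{branch}_lmin"].to_numpy()
            if x.size < 2:  # a single EF level fits no line
                slope = intercept = r2 = float("nan")
            else:
                slope, intercept = np.polyfit(x, y, 1)
                resid = y - (slope * x + intercept)
                ss_tot = float(np.sum((y - y.mean()) ** 2))
                r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            fit_rows.append({"label": label, "branch": branch, "slope": slope,
                             "intercept_lmin": intercept, "r_squared": r2})
    pd.DataFrame(fit_rows).to_csv(d / "flow_vs_ef_fits.csv", index=False)
    ws.to_csv(d / "watershed_zones.csv", index=False)

    summary = {
        "healthy_peak_root_pressure_mmhg": {
            lab: float(v) for lab, v in healthy["peak_root_pressure_mmhg"].items()},
        "ecmo_subset": sorted(set(ecmo["label"]) - {"template"}),
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if man is not None:
        for p in sorted(d.iterdir()):
            man.record(out, p)
        man.timestamps["report"] = _now()
    return d


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute the full study and return the saved manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(
        package_version=_version(), seed=cfg.seed,
        config=_jsonable(dataclasses.asdict(cfg)),
        stage_seeds={s: cfg.stage_seed(s) for s in STAGES},
    )
    try:
        spec, geoms = _stage_generate(cfg, out, man)
        model, augmented = _stage_ssm(cfg, spec, geoms, out, man)
        table = _stage_morpho(cfg, augmented, out, man)
        labels = _stage_select(cfg, table, out, man)
        wk, healthy_flows = _stage_healthy(cfg, model, augmented, labels, out, man)
        _stage_ecmo(cfg, model, augmented, wk, healthy_flows, out, man)
        _stage_report(out, man)
    except Exception as exc:
        man.timestamps["failed"] = _now()
        man.save(out)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    man.save(out)
    return man


def report(out_dir: str | Path) -> Path:
    """(Re)build the report tables from a completed run's stage outputs."""
    return _stage_report(Path(out_dir))


def _version() -> str:
    from . import __version__

    return __version__
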