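"""Config-driven orchestration of the full analysis battery.

One call runs, for every trajectory in the config: subdomain-resolved RMSD
series (with moving averages), the two active-site opening distances,
essential-dynamics PCA with eigenvalue fractions and the mode-1 projection;
then, against a designated reference run: cross-projection of every run
onto the reference's PC1, subspace overlap of that mode with each run's
PCs 1-2, the Pearson correlation between cross-projection and empty-site
opening, a hinge analysis between the reference mode's projection extremes,
and a mode-interpolation multi-model PDB. Outputs are CSV/JSON/PDB files
plus a manifest with content hashes.

Defaults follow the conventions of the analyses this toolkit implements:
frames subsampled to 75 ps for PCA, RMSD moving average period 20, hinge
tolerance 0.4.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .errors import ConfigError
from .geometry import moving_average, rmsd_series
from .hinge import analyse_mode_extremes, report_to_dict
from .io import Structure, Trajectory, subsample, write_pdb, write_timeseries_csv
from .observables import opening_distance_series
from .pca import PCAModel, extreme_frames, fit_pca, pearson_correlation, project, \
    interpolate_mode, subspace_overlap
from .scheme import AtomSelection, ResidueScheme, select_calpha, select_dimer_calpha

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Inputs and parameters of one analysis batch."""

    topology: str
    trajectories: dict[str, str]          # run label -> DCD or multi-model PDB
    output_dir: str = "nbdtraj_out"
    reference_run: str | None = None      # default: first label
    pca_interval_ps: float = 75.0
    moving_average_period: int = 20
    hinge_tolerance: float = 0.4
    pca_mode: int = 1
    n_inner_interpolated: int = 8
    step_fs: float = tio.DEFAULT_STEP_FS
    save_interval_steps: int = tio.DEFAULT_SAVE_INTERVAL_STEPS
    seed: int = 0
    scheme: ResidueScheme = field(default_factory=ResidueScheme)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ConfigError("config lists no trajectories")
        if self.reference_run is None:
            self.reference_run = next(iter(self.trajectories))
        if self.reference_run not in self.trajectories:
            raise ConfigError(f"reference_run {self.reference_run!r} is not a listed run")
        if self.pca_interval_ps <= 0 or self.moving_average_period < 1:
            raise ConfigError("pca_interval_ps must be > 0 and moving_average_period >= 1")
        if not 0 < self.hinge_tolerance <= 1:
            raise ConfigError("hinge_tolerance must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scheme_overrides = raw.pop("scheme", None)
        if scheme_overrides:
            ranges = {k: tuple(tuple(r) for r in v) if isinstance(v, list) else v
                      for k, v in scheme_overrides.items()}
            raw["scheme"] = ResidueScheme(**ranges)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _load_trajectory(path: str, topology: Structure,
                     config: AnalysisConfig) -> Trajectory:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"trajectory file missing: {p}")
    if p.suffix.lower() == ".dcd":
        return tio.read_dcd(p, topology, step_fs=config.step_fs,
                            save_interval_steps=config.save_interval_steps)
    obj = tio.read_pdb(p)
    if isinstance(obj, Structure):
        raise ConfigError(f"{p}: single-model PDB is not a trajectory")
    interval = config.step_fs * config.save_interval_steps * 1e-3
    return Trajectory(obj.topology, obj.frames,
                      np.arange(obj.n_frames) * interval,
                      step_fs=config.step_fs,
                      save_interval_steps=config.save_interval_steps)


def analyse_runs(topology: Structure, runs: dict[str, Trajectory],
                 config: AnalysisConfig) -> dict:
    """Run the full battery in memory; returns a nested results dict.

    This is the pipeline's core; :func:`run_analysis` adds file loading and
    the output bundle around it.
    """
    scheme = config.scheme
    ref_label = config.reference_run
    if ref_label not in runs:
        raise ConfigError(f"reference run {ref_label!r} not among runs")

    sel_all = select_dimer_calpha(topology, scheme, label="CA:all")
    ca_mask = topology.atom_names.astype(str) == "CA"
    monomer_sels = {
        c: AtomSelection(f"CA:{c}", tuple(int(i) for i in np.flatnonzero(
            ca_mask & (topology.chain_ids.astype(str) == c))))
        for c in scheme.chains}
    core_sels = {c: select_calpha(topology, c, scheme.core, label=f"core:{c}")
                 for c in scheme.chains}
    helical_sels = {c: select_calpha(topology, c, scheme.helical_rmsd,
                                     label=f"helical:{c}")
                    for c in scheme.chains}

    results: dict = {"runs": {}, "cross": {}, "parameters": {
        "pca_interval_ps": config.pca_interval_ps,
        "moving_average_period": config.moving_average_period,
        "hinge_tolerance": config.hinge_tolerance,
        "reference_run": ref_label,
    }}

    models: dict[str, PCAModel] = {}
    sub: dict[str, Trajectory] = {}
    for label, traj in runs.items():
        logger.info("run %s: subsampling to %g ps and computing series",
                    label, config.pca_interval_ps)
        s = subsample(traj, config.pca_interval_ps) \
            if traj.n_frames > 1 else traj
        sub[label] = s

        rmsd_panel = {"dimer": rmsd_series(s, sel_all, sel_all, topology)}
        for c in scheme.chains:
            rmsd_panel[f"monomer_{c}"] = rmsd_series(
                s, monomer_sels[c], monomer_sels[c], topology)
            rmsd_panel[f"core_{c}"] = rmsd_series(
                s, core_sels[c], core_sels[c], topology)
            rmsd_panel[f"helical_{c}"] = rmsd_series(
                s, helical_sels[c], helical_sels[c], topology)
        period = min(config.moving_average_period, s.n_frames)
        smoothed = {k: moving_average(v, period) for k, v in rmsd_panel.items()}

        opening = opening_distance_series(s, scheme)
        model = fit_pca(s, sel_all, topology, source_label=label)
        models[label] = model
        proj1 = project(s, model, config.pca_mode)

        results["runs"][label] = {
            "times_ps": s.times,
            "rmsd": rmsd_panel,
            "rmsd_moving_average": smoothed,
            "moving_average_period": period,
            "opening": {k: v.values for k, v in opening.items()},
            "pca_fractions": model.fractions,
            "projection_mode1": proj1.values,
        }

    ref_model = models[ref_label]
    ref_mode_vec = ref_model.modes[config.pca_mode - 1]
    for label, s in sub.items():
        cross = project(s, ref_model, config.pca_mode)
        overlap = subspace_overlap(ref_mode_vec, models[label], k=2)
        apo = results["runs"][label]["opening"]["site_apo"]
        try:
            r = pearson_correlation(cross.values, apo)
        except ValueError:
            r = float("nan")  # zero-variance control runs have no correlation
        results["cross"][label] = {
            "projection": cross.values,
            "subspace_overlap_k2": overlap,
            "pearson_r_apo_opening": r,
        }

    logger.info("hinge analysis on %s mode-%d extremes", ref_label, config.pca_mode)
    report = analyse_mode_extremes(sub[ref_label], ref_model, config.pca_mode,
                                   tolerance=config.hinge_tolerance)
    results["hinge"] = report_to_dict(report)
    results["hinge_report"] = report

    proj_ref = results["runs"][ref_label]["projection_mode1"]
    results["mode_interpolation"] = interpolate_mode(
        ref_model, config.pca_mode, float(np.min(proj_ref)),
        float(np.max(proj_ref)), config.n_inner_interpolated)
    results["models"] = models
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_analysis(config: AnalysisConfig) -> dict:
    """Load inputs, run :func:`analyse_runs`, and write the output bundle.

    Returns the manifest dict. Any stage failure raises with the stage name
    prefixed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        topo = tio.read_pdb(config.topology)
        if isinstance(topo, Trajectory):
            topo = topo.topology
        runs = {label: _load_trajectory(path, topo, config)
                for label, path in config.trajectories.items()}
        stage = "analyse"
        results = analyse_runs(topo, runs, config)

        stage = "write"
        files: list[Path] = []
        for label, res in results["runs"].items():
            t = res["times_ps"]
            f = out / f"rmsd_{label}.csv"
            write_timeseries_csv(f, t, res["rmsd"])
            files.append(f)
            period = res["moving_average_period"]
            tm = t[period - 1:]
            f = out / f"rmsd_moving_average_{label}.csv"
            write_timeseries_csv(f, tm, res["rmsd_moving_average"])
            files.append(f)
            f = out / f"opening_{label}.csv"
            write_timeseries_csv(f, t, {f"{k}_A": v for k, v in res["opening"].items()})
            files.append(f)
            f = out / f"projection_mode1_{label}.csv"
            write_timeseries_csv(f, t, {"projection_A": res["projection_mode1"]})
            files.append(f)
            f = out / f"cross_projection_{label}.csv"
            write_timeseries_csv(f, t, {"projection_A":
                                        results["cross"][label]["projection"]})
            files.append(f)

        summary = {
            "parameters": results["parameters"],
            "pca_fractions": {label: res["pca_fractions"][:10].tolist()
                              for label, res in results["runs"].items()},
            "cross": {label: {"subspace_overlap_k2": c["subspace_overlap_k2"],
                              "pearson_r_apo_opening": c["pearson_r_apo_opening"]}
                      for label, c in results["cross"].items()},
        }
        f = out / "summary.json"
        f.write_text(json.dumps(summary, indent=2))
        files.append(f)

        f = out / "hinge_report.json"
        f.write_text(json.dumps(results["hinge"], indent=2))
        files.append(f)

        f = out / "mode1_interpolation.pdb"
        tio.write_trajectory_pdb(f, results["mode_interpolation"])
        files.append(f)

        manifest = {
            "outputs": {p.name: _sha256(p) for p in files},
            "parameters": results["parameters"],
            "runs": list(config.trajectories),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
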