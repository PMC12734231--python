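"""Simulate -> analyze -> report orchestration over a synthetic cohort.

``run_simulate`` writes a dataset directory (one sub-directory per
subject/phase with per-frame PLY files, a JSON sidecar and the ground-truth
volume curve CSV, plus a manifest). ``run_analyze`` reads the dataset back,
registers each sequence and computes volume/filling indices, global strain,
hemodynamic-force parameters and VFT into a long-format cohort table; failed
subjects are quarantined, not fatal. ``run_report`` emits the mean +/- SD
summary, the HR regressions and phase-aggregated strain/force time courses.
Everything is deterministic given the config seed; outputs carry the manifest
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_statistics as cs
from . import flow_metrics as fm
from . import hemodynamic_forces as hdf
from . import mesh_kinematics as mk
from . import strain_analysis as sa
from . import synthetic_cohort as sc

__all__ = ["RunConfig", "ConfigError", "run_simulate", "run_analyze", "run_report"]

log = logging.getLogger("lvmech")


class ConfigError(ValueError):
    """User-facing configuration problem."""


_PHASE_KEYS = {"hr", "edv", "esv", "ef", "n_frames", "e_a_ratio", "systolic_fraction"}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``phase_params`` optionally overrides per-phase generator defaults
    (mean/SD pairs for hr, edv, esv, n_frames; scalars for e_a_ratio and
    systolic_fraction). ``mv_area_mm2`` sets the effective mitral orifice
    area used for VFT; ``rho``/``g`` the force normalization constants.
    """

    seed: int = 0
    n_subjects: int = 19
    phases: tuple = tuple(
        p.value for p in (
            sc.PhaseLabel.REST, sc.PhaseLabel.MID, sc.PhaseLabel.PEAK,
            sc.PhaseLabel.RECOVERY5, sc.PhaseLabel.RECOVERY10,
        )
    )
    include_control: bool = True
    control_n_subjects: int = 25
    phase_params: dict = field(default_factory=dict)
    mesh_n_long: int = 24
    mesh_n_circ: int = 48
    mv_area_mm2: float = 400.0
    rho: float = hdf.RHO_BLOOD
    g: float = hdf.G_STANDARD
    harmonics: int | None = None
    resample_frames: int = 32

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(f"config is not valid JSON: {e}") from e
        return cls.from_dict(d)

    def validate(self) -> None:
        valid_phases = {p.value for p in sc.PhaseLabel}
        for ph in self.phases:
            if ph not in valid_phases:
                raise ConfigError(f"invalid phase name {ph!r}; valid: {sorted(valid_phases)}")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        for ph, over in self.phase_params.items():
            if ph not in valid_phases:
                raise ConfigError(f"phase_params: invalid phase name {ph!r}")
            bad = set(over) - _PHASE_KEYS
            if bad:
                raise ConfigError(f"phase_params[{ph}]: unknown keys {sorted(bad)}")
        if self.mv_area_mm2 <= 0 or self.rho <= 0 or self.g <= 0:
            raise ConfigError("mv_area_mm2, rho and g must be positive")
        if self.resample_frames < 10:
            raise ConfigError("resample_frames must be >= 10")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["phases"] = list(d["phases"])
        return d


def _phase_overrides(cfg: RunConfig, phase: sc.PhaseLabel) -> dict | None:
    over = cfg.phase_params.get(phase.value)
    if over is None:
        return None
    out = {}
    for k, v in over.items():
        out[k] = tuple(v) if isinstance(v, (list, tuple)) else v
    return out


def _manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_simulate(cfg: RunConfig, out_dir, *, force: bool = False) -> Path:
    """Generate the cohort dataset on disk; returns the dataset directory."""
    out_dir = Path(out_dir)
    manifest_file = out_dir / "manifest.json"
    if manifest_file.exists() and not force:
        raise ConfigError(f"{manifest_file} exists; pass force=True/--force to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    phases = [sc.PhaseLabel(p) for p in cfg.phases]
    entries = []

    def simulate_one(sid, phase, spec):
        spec = _with_mesh_resolution(spec, cfg)
        seq, lm, gt = sc.generate_ventricle_sequence(spec)
        rel = f"{sid}_{phase.value}"
        mk.write_mesh_sequence(
            out_dir / rel, seq, lm,
            extras={**seq.metadata, "subject": sid, "phase": phase.value},
        )
        pd.DataFrame(
            {"time_s": gt.times, "volume_ml": gt.volume, "dvdt_ml_s": gt.dvdt}
        ).to_csv(out_dir / rel / "ground_truth_volume.csv", index=False)
        entries.append({"subject": sid, "phase": phase.value, "path": rel,
                        "spec": sc._spec_to_dict(spec)})

    for k in range(cfg.n_subjects):
        sid = f"S{k:03d}"
        for phase in phases:
            spec = sc.sample_spec(rng, phase, _phase_overrides(cfg, phase), seed=cfg.seed)
            simulate_one(sid, phase, spec)
    if cfg.include_control:
        for k in range(cfg.control_n_subjects):
            sid = f"C{k:03d}"
            phase = sc.PhaseLabel.CONTROL
            spec = sc.sample_spec(rng, phase, _phase_overrides(cfg, phase), seed=cfg.seed)
            simulate_one(sid, phase, spec)

    manifest = {"config": cfg.to_dict(), "entries": entries}
    manifest["hash"] = _manifest_hash({"config": manifest["config"],
                                       "entries": manifest["entries"]})
    manifest_file.write_text(json.dumps(manifest, indent=1))
    log.info("simulate: %d sequences in %.1fs", len(entries), time.perf_counter() - t0)
    return out_dir


def _with_mesh_resolution(spec: sc.VentricleSpec, cfg: RunConfig) -> sc.VentricleSpec:
    from dataclasses import replace

    return replace(spec, n_long=cfg.mesh_n_long, n_circ=cfg.mesh_n_circ)


def analyze_sequence(seq: mk.MeshSequence, lm: mk.Landmarks, cfg: RunConfig) -> dict:
    """All per-subject metrics for one cycle. Returns a metric -> value dict
    in reporting units (mL, %, bpm, dimensionless)."""
    seq, lm = mk.register(seq, lm)
    vc = mk.volume_curve(seq)
    useq = mk.resample_cycle(seq, cfg.resample_frames)

    strain = sa.global_strain_series(useq)
    series = hdf.hdf_time_series(useq, rho=cfg.rho, g=cfg.g, harmonics=cfg.harmonics)
    pars = hdf.hdf_parameters(series)
    flow = fm.transmitral_flow_from_volume_curve(vc, cfg.mv_area_mm2)
    vft = fm.vortex_formation_time(flow)

    i_es = strain.i_es
    metrics = {
        "HR": 60.0 / seq.period,
        "EDV": vc.edv,
        "ESV": vc.esv,
        "SV": vc.stroke_volume,
        "EF": 100.0 * vc.ejection_fraction,
        "GPS": strain.gps[i_es],
        "GSS": strain.gss[i_es],
        "GLS": strain.gls[i_es],
        "GCS": strain.gcs[i_es],
        "LVLF": pars.lvlf,
        "LVsysLF": pars.lvsyslf,
        "LVdiaLF": pars.lvdialf,
        "LVsysIm": pars.lvsysim,
        "LVs": pars.lvs,
        "LVdiaIm": pars.lvdiaim,
        "VFT": vft,
        "E/A": vc.e_a_ratio,
    }
    aux = {
        "strain_series": strain,
        "hdf_series": series,
        "volume_curve": vc,
        "vft_label": fm.classify_vft(vft),
    }
    return metrics, aux


def run_analyze(data_dir, out_dir) -> pd.DataFrame:
    """Analyze every dataset entry into a long-format cohort table.

    Per-entry failures are logged and quarantined in ``quarantine.json``; the
    run continues. Writes ``cohort_table.csv`` plus per-subject series CSVs.
    """
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    manifest_file = data_dir / "manifest.json"
    if not manifest_file.exists():
        raise ConfigError(f"no manifest at {manifest_file}")
    manifest = json.loads(manifest_file.read_text())
    cfg = RunConfig.from_dict(manifest["config"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "series").mkdir(exist_ok=True)

    t0 = time.perf_counter()
    records, quarantined = [], []
    for entry in manifest["entries"]:
        sid, phase, rel = entry["subject"], entry["phase"], entry["path"]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", mk.QCWarning)
                seq, lm = mk.read_mesh_sequence(data_dir / rel)
            qc = bool(seq.n_frames < mk.MIN_FRAMES)
            metrics, aux = analyze_sequence(seq, lm, cfg)
        except Exception as e:  # quarantine-not-abort policy for cohort runs
            log.warning("quarantined %s: %s", rel, e)
            quarantined.append({"path": rel, "error": str(e)})
            continue
        for m, v in metrics.items():
            records.append({"subject": sid, "phase": phase, "metric": m,
                            "value": np.nan if v is None else v, "qc_low_frames": qc})
        s = aux["strain_series"]
        h = aux["hdf_series"]
        pd.DataFrame({
            "phase_fraction": s.times / seq.period,
            "gps_pct": s.gps, "gss_pct": s.gss, "gls_pct": s.gls, "gcs_pct": s.gcs,
        }).to_csv(out_dir / "series" / f"{rel}_strain.csv", index=False)
        pd.DataFrame({
            "phase_fraction": h.times / h.period,
            "fx_pct": h.f_percent[:, 0], "fy_pct": h.f_percent[:, 1],
            "fz_pct": h.f_percent[:, 2], "volume_ml": h.volume_ml,
        }).to_csv(out_dir / "series" / f"{rel}_hdf.csv", index=False)

    table = pd.DataFrame.from_records(records)
    table.to_csv(out_dir / "cohort_table.csv", index=False)
    (out_dir / "quarantine.json").write_text(json.dumps(quarantined, indent=1))
    (out_dir / "analysis_manifest.json").write_text(json.dumps(
        {"hash": manifest.get("hash"), "n_analyzed": len(manifest["entries"]) - len(quarantined),
         "n_quarantined": len(quarantined)}, indent=1))
    log.info("analyze: %d entries (%d quarantined) in %.1fs",
             len(manifest["entries"]), len(quarantined), time.perf_counter() - t0)
    return table


def run_report(results_dir, out_dir) -> pd.DataFrame:
    """Summarize an analysis directory: mean +/- SD table (CSV + Markdown),
    HR-vs-VFT (and HR-vs-vorticity when present) regression CSVs, and
    phase-aggregated strain/HDF time-course bands."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir)
    table_file = results_dir / "cohort_table.csv"
    if not table_file.exists():
        raise ConfigError(f"no cohort table at {table_file}")
    table = pd.read_csv(table_file)
    if table.empty:
        raise ConfigError("empty cohort table")
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = cs.summary_table(table)
    flat = summary.copy()
    flat.columns = ["_".join(c) for c in summary.columns]
    flat.to_csv(out_dir / "summary_table.csv")
    (out_dir / "summary_table.md").write_text(cs.format_summary_markdown(summary))

    wide = table.pivot_table(index=["subject", "phase"], columns="metric", values="value")
    for metric, fname in (("VFT", "hr_vs_vft.csv"), ("omega_bar_peak", "hr_vs_vorticity.csv")):
        if metric in wide.columns and "HR" in wide.columns:
            sub = wide[["HR", metric]].dropna()
            if len(sub) >= 3 and np.ptp(sub["HR"].to_numpy()) > 0:
                slope, intercept, r2, p = cs.linear_fit(sub[metric], sub["HR"])
                sub.to_csv(out_dir / fname)
                (out_dir / fname.replace(".csv", "_fit.json")).write_text(json.dumps(
                    {"x": metric, "y": "HR", "slope": slope, "intercept": intercept,
                     "r_squared": r2, "p_value": p, "n": len(sub)}, indent=1))

    series_dir = results_dir / "series"
    if series_dir.exists():
        for kind in ("strain", "hdf"):
            _aggregate_series(series_dir, kind, out_dir)
    return summary


def _aggregate_series(series_dir: Path, kind: str, out_dir: Path) -> None:
    by_phase: dict[str, list[pd.DataFrame]] = {}
    for f in sorted(series_dir.glob(f"*_{kind}.csv")):
        phase = f.stem[: -len(f"_{kind}")].split("_")[-1]
        by_phase.setdefault(phase, []).append(pd.read_csv(f))
    for phase, dfs in by_phase.items():
        if not dfs:
            continue
        cols = [c for c in dfs[0].columns if c != "phase_fraction"]
        n = min(len(d) for d in dfs)
        stack = {c: np.stack([d[c].to_numpy()[:n] for d in dfs]) for c in cols}
        out = {"phase_fraction": dfs[0]["phase_fraction"].to_numpy()[:n]}
        for c in cols:
            out[f"{c}_mean"] = stack[c].mean(axis=0)
            out[f"{c}_sd"] = stack[c].std(axis=0, ddof=1) if len(dfs) > 1 else 0.0
        pd.DataFrame(out).to_csv(out_dir / f"{kind}_band_{phase}.csv", index=False)
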