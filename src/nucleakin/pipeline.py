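"""End-to-end orchestration: CVs -> MSM -> PCCA+ -> TPT -> report.

The pipeline consumes either a synthetic ground-truth network (generating
CV trajectories internally), pre-computed CV tables, or molecular
trajectories (which are first passed through detection and featurization).
Stages write cached artifacts tagged with a configuration hash; a resume
against a stale cache is refused rather than silently recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import msm as msm_mod
from . import tpt as tpt_mod
from .cv_featurize import CVSeries, SELECTED5, compute_cvs
from .cv_select import spectral_oasis_select
from .errors import ConfigError, PipelineCacheError
from .ice_detect import DetectionParams, classify
from .pcca import pcca_plus
from .synthetic import build_two_pathway_network, emit_trajectories
from .trajectory_io import read_lammps_dump, read_xyz

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII",
          "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys in a TOML file are rejected.  All randomness flows from
    ``seed``; ``temperature`` is a label carried into the report.
    """

    seed: int = 1
    temperature: float = 230.0
    out_dir: str = "pipeline_out"
    # input
    input_mode: str = "synthetic_network"   # synthetic_network | cv_table | trajectory
    cv_table: Optional[str] = None
    trajectory: Optional[str] = None
    trajectory_format: str = "xyz"          # xyz | lammps
    box: Optional[list] = None
    # synthetic network
    pathway_split: float = 0.5
    metastability: float = 0.95
    n_traj: int = 10
    n_steps: int = 100_000
    # featurization / selection
    featurize_mode: str = "selected5"
    select_lag: float = 10.0      # ps
    n_select: int = 5
    n_slow: int = 3
    run_selection: bool = False
    # MSM
    n_states: int = 100
    msm_lag: int = 10             # frames
    lag_time: float = 1.0         # ps per frame
    reversible: bool = True
    its_lags: list = field(default_factory=lambda: [1, 2, 5, 10, 20, 50])
    ck_kmax: int = 5
    # PCCA / TPT
    n_macro: int = 8
    # "first_cv": source = macro with the smallest mean of the first CV
    # (the nucleus size for the standard CV set), sinks = the two largest;
    # "index": use source_macro / sink_macros literally
    endpoint_selection: str = "first_cv"
    source_macro: int = 0
    sink_macros: list = field(default_factory=lambda: [6, 7])
    min_flux_fraction: float = 0.0
    ts_window: list = field(default_factory=lambda: [0.45, 0.55])
    volume_m3: float = 2.239e-25  # 5.43 x 5.89 x 7.0 nm^3 study box

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self, *fields_: str) -> str:
        payload = {f: getattr(self, f) for f in sorted(fields_)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_STAGE_FIELDS = {
    "cvs": ("seed", "input_mode", "cv_table", "trajectory", "trajectory_format",
            "box", "pathway_split", "metastability", "n_traj", "n_steps",
            "featurize_mode", "lag_time"),
    "msm": ("n_states", "msm_lag", "reversible", "run_selection",
            "select_lag", "n_select", "n_slow"),
    "macro": ("n_macro",),
    "tpt": ("endpoint_selection", "source_macro", "sink_macros",
            "min_flux_fraction", "ts_window", "volume_m3"),
}


class Pipeline:
    """Stage runner with hash-tagged artifact caching."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        self.timings: dict[str, float] = {}

    # -- caching helpers ---------------------------------------------------
    def _stage_hash(self, stage: str) -> str:
        fields_: tuple[str, ...] = ()
        for s, fl in _STAGE_FIELDS.items():
            fields_ += fl
            if s == stage:
                break
        return self.config.digest(*fields_)

    def _check_cache(self, stage: str, path: Path) -> bool:
        h = self._stage_hash(stage)
        if path.exists():
            recorded = self.manifest.get(stage)
            if recorded is None:
                raise PipelineCacheError(
                    f"artifact {path} exists but stage {stage!r} is not in the manifest"
                )
            if recorded != h:
                raise PipelineCacheError(
                    f"stage {stage!r} cache is stale (config changed); "
                    f"delete {path} to recompute"
                )
            return True
        return False

    def _record(self, stage: str, t0: float) -> None:
        self.manifest[stage] = self._stage_hash(stage)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))
        self.timings[stage] = time.perf_counter() - t0

    # -- stages ------------------------------------------------------------
    def stage_cvs(self) -> list[CVSeries]:
        cfg = self.config
        path = self.out / "cvs.parquet"
        t0 = time.perf_counter()
        if self._check_cache("cvs", path):
            df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
            series = [
                CVSeries(g.drop(columns="traj").reset_index(drop=True), stride=cfg.lag_time)
                for _, g in df.groupby("traj", sort=True)
            ]
            self.timings["cvs"] = time.perf_counter() - t0
            return series
        if cfg.input_mode == "synthetic_network":
            net = build_two_pathway_network(cfg.pathway_split, cfg.metastability, seed=cfg.seed)
            series, _ = emit_trajectories(net, cfg.n_traj, cfg.n_steps, seed=cfg.seed,
                                          stride=cfg.lag_time)
        elif cfg.input_mode == "cv_table":
            if not cfg.cv_table:
                raise ConfigError("cv_table input mode requires a cv_table path")
            df = pd.read_csv(cfg.cv_table, sep="\t")
            groups = df.groupby("traj", sort=True) if "traj" in df else [(0, df)]
            series = [
                CVSeries(g.drop(columns=[c for c in ("traj",) if c in g]).reset_index(drop=True),
                         stride=cfg.lag_time)
                for _, g in groups
            ]
        elif cfg.input_mode == "trajectory":
            if not cfg.trajectory:
                raise ConfigError("trajectory input mode requires a trajectory path")
            reader = read_xyz if cfg.trajectory_format == "xyz" else read_lammps_dump
            kwargs = {"box": cfg.box} if cfg.trajectory_format == "xyz" and cfg.box else {}
            traj = reader(cfg.trajectory, **kwargs)
            labels = [classify(f, DetectionParams()) for f in traj]
            series = [compute_cvs(labels, mode=cfg.featurize_mode,
                                  frames=list(traj), stride=cfg.lag_time)]
        else:
            raise ConfigError(f"unknown input mode {cfg.input_mode!r}")
        parts = [s.data.assign(traj=k) for k, s in enumerate(series)]
        pd.concat(parts, ignore_index=True).to_parquet(path)
        self._record("cvs", t0)
        return series

    def stage_msm(self, series: list[CVSeries]):
        cfg = self.config
        path = self.out / "msm.h5"
        t0 = time.perf_counter()
        selection_report = None
        if cfg.run_selection and series[0].data.shape[1] > cfg.n_select:
            sel = spectral_oasis_select(series, tau=cfg.select_lag,
                                        n_select=cfg.n_select, m=cfg.n_slow)
            selection_report = {
                "selected": list(sel.selected_names),
                "timescales": {str(k): v.tolist() for k, v in sel.timescale_curves.items()},
            }
            series = [s.subset(sel.selected_names) for s in series]
        if self._check_cache("msm", path):
            model = msm_mod.load_model(path)
        else:
            model = msm_mod.build_msm(series, n_states=cfg.n_states, lag=cfg.msm_lag,
                                      seed=cfg.seed, reversible=cfg.reversible,
                                      lag_time=cfg.lag_time)
            msm_mod.save_model(model, path)
            self._record("msm", t0)
        its = msm_mod.implied_timescales(
            model.dtrajs, [l for l in cfg.its_lags if any(len(d) > l for d in model.dtrajs)],
            m=min(cfg.n_slow, model.n_states - 1), lag_time=cfg.lag_time,
        )
        return model, its, selection_report

    def stage_macro(self, model):
        cfg = self.config
        t0 = time.perf_counter()
        macro = pcca_plus(model.T, model.pi, min(cfg.n_macro, model.n_states))
        # relabel macro-states along the nucleation progression: macro 0 has
        # the smallest pi-weighted mean of the first CV (nucleus size)
        cv0 = model.centers[model.active, 0]
        mean0 = np.array([
            float(model.pi[macro.crisp == a] @ cv0[macro.crisp == a]
                  / max(model.pi[macro.crisp == a].sum(), 1e-300))
            for a in range(macro.n_macro)
        ])
        order = np.argsort(mean0)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        macro.membership = macro.membership[:, order]
        macro.crisp = rank[macro.crisp]
        macro.macro_pi = macro.macro_pi[order]
        macro.macro_T = macro.macro_T[np.ix_(order, order)]
        self._record("macro", t0)
        return macro

    def stage_tpt(self, model, macro):
        cfg = self.config
        t0 = time.perf_counter()
        if cfg.endpoint_selection == "first_cv":
            # macro-states are already ordered by nucleus size (stage_macro)
            source, sinks = 0, [macro.n_macro - 2, macro.n_macro - 1]
        elif cfg.endpoint_selection == "index":
            source, sinks = cfg.source_macro, list(cfg.sink_macros)
        else:
            raise ConfigError(f"unknown endpoint_selection {cfg.endpoint_selection!r}")
        self.endpoints = (source, sinks)
        A = macro.states_of(source)
        B = np.concatenate([macro.states_of(s) for s in sinks])
        res = tpt_mod.analyze(model.T, model.pi, A, B,
                              min_fraction=cfg.min_flux_fraction, crisp=macro.crisp)
        ts = tpt_mod.transition_state_microstates(res.q_plus, tuple(cfg.ts_window))
        # macro-pair MFPTs in physical time
        n_macro = macro.n_macro
        mfpt_matrix = np.zeros((n_macro, n_macro))
        for b in range(n_macro):
            tgt = macro.states_of(b)
            if tgt.size == 0:
                continue
            m = tpt_mod.mfpt(model.T, tgt, lag_time=model.lag * model.lag_time)
            for a in range(n_macro):
                src = macro.states_of(a)
                if a == b or src.size == 0:
                    continue
                w = model.pi[src] / model.pi[src].sum()
                mfpt_matrix[a, b] = float(w @ m[src])
        # nucleation rate from the source -> sink MFPT (ps -> s)
        src = A
        w = model.pi[src] / model.pi[src].sum()
        m = tpt_mod.mfpt(model.T, B, lag_time=model.lag * model.lag_time)
        mfpt_ps = float(w @ m[src])
        rate = tpt_mod.nucleation_rate(mfpt_ps * 1e-12, cfg.volume_m3)
        self._record("tpt", t0)
        return res, ts, mfpt_matrix, rate


def _compress(seq: list[str]) -> list[str]:
    """Drop consecutive duplicates (micro path -> macro-level path)."""
    out = seq[:1]
    for x in seq[1:]:
        if x != out[-1]:
            out.append(x)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write a JSON report plus the resolved config."""
    pipe = Pipeline(config)
    series = pipe.stage_cvs()
    model, its, selection = pipe.stage_msm(series)
    macro = pipe.stage_macro(model)
    res, ts_states, mfpt_matrix, rate = pipe.stage_tpt(model, macro)

    names = _ROMAN[: macro.n_macro]
    flux_table = []
    F = res.macro_net_flux
    for a in range(macro.n_macro):
        for b in range(macro.n_macro):
            if F[a, b] > 0:
                flux_table.append(
                    {"from": names[a], "to": names[b],
                     "net_flux": F[a, b], "fraction": F[a, b] / max(res.total_flux, 1e-300)}
                )
    report = {
        "temperature_K": config.temperature,
        "seed": config.seed,
        "n_microstates": int(model.n_states),
        "n_macrostates": int(macro.n_macro),
        "macro_populations": {names[k]: float(p) for k, p in enumerate(macro.macro_pi)},
        "tpt_source": names[pipe.endpoints[0]],
        "tpt_sinks": [names[s] for s in pipe.endpoints[1]],
        "implied_timescales": {
            "lags": its.lags.tolist(),
            "timescales": np.where(np.isnan(its.timescales), None, its.timescales).tolist(),
        },
        "selection": selection,
        "total_flux": res.total_flux,
        "flux_table": flux_table,
        "pathways": [
            {"states": _compress([names[macro.crisp[s]] for s in path]),
             "micro_path_len": len(path),
             "flux": f, "fraction": f / max(res.total_flux, 1e-300)}
            for path, f in res.pathways[:10]
        ],
        "transition_state_microstates": [int(s) for s in ts_states],
        "mfpt_matrix_ps": mfpt_matrix.tolist(),
        "nucleation_rate_per_s_m3": rate,
        "timings_s": pipe.timings,
    }
    out = Path(config.out_dir)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    (out / "resolved_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1)
    )
    return report
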