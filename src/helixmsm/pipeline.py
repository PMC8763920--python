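"""End-to-end pipeline: simulate -> coordinates -> features -> tICA ->
k-centers -> MSM -> helicity profiles, from a single declarative config.

Every stage seed is derived deterministically from the global seed and the
stage coordinates (system index, stage name, item index), so a rerun with
the same config is bit-identical and individual stages can be re-derived in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import helicity as hel
from . import msm as msmlib
from .cluster import assign, kcenters_fit
from .featurize import (compute_pair_features, discard_equilibration,
                        select_feature_atoms)
from .geometry import BackboneGeometry, build_coordinates
from .helixcoil import HelixCoilParams, simulate_helix_coil
from .tica import fit_tica, project

__all__ = ["SystemConfig", "PipelineConfig", "validate_config",
           "run_pipeline", "derive_seed", "analyze_state_trajectories"]

_STAGE_CODES = {"simulate": 1, "coordinates": 2, "features": 3, "tica": 4,
                "cluster": 5, "msm": 6, "bootstrap": 7}


def derive_seed(global_seed: int, *keys: int) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed and
    integer stage coordinates."""
    ss = np.random.SeedSequence(entropy=[int(global_seed) & 0x7FFFFFFF,
                                         *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SystemConfig:
    name: str
    n_res: int = 15
    sigma: float = 0.01
    s: float = 1.1
    staple: Optional[Tuple[int, int]] = None
    staple_bonus: float = 1.0
    flip_attempts_per_frame: int = 15
    frame_dt: float = 0.5  # ns

    def helix_coil_params(self, seed: int = 0) -> HelixCoilParams:
        staple = tuple(self.staple) if self.staple is not None else None
        return HelixCoilParams(
            n_res=self.n_res, sigma=self.sigma, s=self.s, staple=staple,
            staple_bonus=self.staple_bonus,
            flip_attempts_per_frame=self.flip_attempts_per_frame,
            frame_dt=self.frame_dt, seed=seed,
        )


@dataclass
class PipelineConfig:
    """Run parameters; defaults mirror the reference analysis: tICA lag
    5 ns, 4 components, 50 k-centers states, 5 bootstrap replicates,
    100 ns equilibration discard."""

    systems: List[SystemConfig]
    seed: int = 0
    n_trajectories: int = 50
    n_frames: int = 2400            # saved frames per trajectory, pre-discard
    t_eq: float = 100.0             # ns discarded from each trajectory
    tica_lag: float = 5.0           # ns
    n_components: int = 4
    cluster_k: int = 50
    msm_lags: List[float] = field(
        default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0]
    )
    msm_lag: float = 25.0           # ns, final-model lag
    reversible: bool = False
    n_boot: int = 5
    jitter_sd: float = 0.1          # A of Cartesian noise on built coordinates
    use_dssp_labels: bool = False   # helicity from geometric assignment
                                    # instead of generator states
    output_dir: str = "helixmsm_out"

    def lag_frames(self, lag_ns: float, frame_dt: float) -> int:
        frames = int(round(lag_ns / frame_dt))
        if frames < 1:
            raise ValueError(
                f"lag {lag_ns} ns is below one frame ({frame_dt} ns)"
            )
        return frames


_KNOWN_KEYS = {
    "systems", "seed", "n_trajectories", "n_frames", "t_eq", "tica_lag",
    "n_components", "cluster_k", "msm_lags", "msm_lag", "reversible",
    "n_boot", "jitter_sd", "use_dssp_labels", "output_dir",
}
_KNOWN_SYSTEM_KEYS = {
    "name", "n_res", "sigma", "s", "staple", "staple_bonus",
    "flip_attempts_per_frame", "frame_dt",
}


def validate_config(source) -> PipelineConfig:
    """Build a normalized :class:`PipelineConfig` from a YAML path, YAML
    string, or dict; all validation errors are aggregated into one report.

    An empty file yields the all-defaults config with a single default
    (unstapled) system.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        if os.path.exists(str(source)):
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(str(source))
        raw = raw or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
    errors = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    sys_raw = raw.pop("systems", None)
    if sys_raw is None:
        sys_raw = [{"name": "default"}]
    systems = []
    for i, s in enumerate(sys_raw):
        bad = set(s) - _KNOWN_SYSTEM_KEYS
        if bad:
            errors.append(f"system {i}: unknown keys {sorted(bad)}")
            s = {k: v for k, v in s.items() if k in _KNOWN_SYSTEM_KEYS}
        if "name" not in s:
            s["name"] = f"system{i}"
        try:
            sc = SystemConfig(**s)
            sc.helix_coil_params()  # triggers invariant checks
            systems.append(sc)
        except (TypeError, ValueError) as exc:
            errors.append(f"system {i}: {exc}")
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    try:
        cfg = PipelineConfig(systems=systems, **kwargs)
    except TypeError as exc:
        errors.append(str(exc))
        cfg = None
    if cfg is not None:
        if cfg.cluster_k < 1:
            errors.append(f"cluster_k must be >= 1, got {cfg.cluster_k}")
        if cfg.n_components < 1:
            errors.append("n_components must be >= 1")
        if cfg.n_trajectories < 2:
            errors.append("n_trajectories must be >= 2")
        if cfg.n_boot < 2:
            errors.append("n_boot must be >= 2")
        if cfg.t_eq < 0:
            errors.append("t_eq must be >= 0")
        for sc in cfg.systems:
            if cfg.t_eq >= cfg.n_frames * sc.frame_dt:
                errors.append(
                    f"system {sc.name}: t_eq discards every frame"
                )
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def analyze_state_trajectories(
    state_trajs,
    config: PipelineConfig,
    system_index: int,
    system: SystemConfig,
):
    """Run coordinates -> features -> tICA -> clustering -> MSM -> helicity
    for one system's (already equilibration-trimmed) state trajectories.

    Returns a result dict with the tICA model, cluster model, per-trajectory
    labels, lag-scan table, final MSM, helicity profile and bootstrap
    ensemble.
    """
    seed0 = config.seed
    geom = BackboneGeometry(jitter_sd=config.jitter_sd)
    dt = system.frame_dt

    feature_mats = []
    ss_list = []
    for i, st in enumerate(state_trajs):
        ct = build_coordinates(
            st, geom,
            seed=derive_seed(seed0, system_index,
                             _STAGE_CODES["coordinates"], i),
        )
        atoms = select_feature_atoms(ct.topology)
        feature_mats.append(compute_pair_features(ct, atoms))
        if config.use_dssp_labels:
            ss_list.append(hel.assign_helix(ct).helix)
        else:
            ss_list.append(st.states.astype(bool))

    tica_model = fit_tica(feature_mats,
                          config.lag_frames(config.tica_lag, dt),
                          n_components=config.n_components)
    projections = [project(fm, tica_model) for fm in feature_mats]

    cmod = kcenters_fit(
        np.concatenate(projections, axis=0), config.cluster_k,
        seed=derive_seed(seed0, system_index, _STAGE_CODES["cluster"]),
    )
    labels = [assign(p, cmod) for p in projections]

    lags = [config.lag_frames(l, dt) for l in config.msm_lags]
    scan = msmlib.lag_scan(labels, lags, frame_dt=dt,
                           reversible=config.reversible)

    final_lag = config.lag_frames(config.msm_lag, dt)
    model = msmlib.fit_msm(labels, final_lag, n_states=config.cluster_k,
                           frame_dt=dt, reversible=config.reversible)
    overall, per_res, h_states = hel.msm_helicity_profile(ss_list, labels,
                                                          model)

    def quantity_fn(m, idx):
        out = {}
        ov, pr, _ = hel.msm_helicity_profile(
            [ss_list[i] for i in idx], [labels[i] for i in idx], m)
        out["mean_helicity"] = ov
        out["per_residue_helicity"] = pr
        return out

    boot = msmlib.bootstrap_models(
        labels, final_lag, n_boot=config.n_boot,
        seed=derive_seed(seed0, system_index, _STAGE_CODES["bootstrap"]),
        frame_dt=dt, reversible=config.reversible, quantity_fn=quantity_fn,
    )
    profile = hel.HelicityProfile(
        per_residue=per_res,
        per_residue_sem=boot.sem["per_residue_helicity"],
        overall=overall,
        overall_sem=float(boot.sem["mean_helicity"]),
        state_helicity=h_states,
    )
    return {
        "tica": tica_model,
        "cluster": cmod,
        "labels": labels,
        "lag_scan": scan,
        "msm": model,
        "profile": profile,
        "bootstrap": boot,
    }


def run_pipeline(config: PipelineConfig, output_dir: Optional[str] = None
                 ) -> Dict[str, dict]:
    """Execute all stages for every configured system and write artifacts
    (timescale tables, helicity profiles, provenance) to the output
    directory.  Deterministic for a fixed config."""
    outdir = output_dir or config.output_dir
    os.makedirs(outdir, exist_ok=True)
    results = {}
    for si, system in enumerate(config.systems):
        trajs = []
        for i in range(config.n_trajectories):
            params = system.helix_coil_params()
            st = simulate_helix_coil(
                params, config.n_frames,
                seed=derive_seed(config.seed, si, _STAGE_CODES["simulate"],
                                 i),
            )
            trajs.append(discard_equilibration(st, config.t_eq))
        try:
            res = analyze_state_trajectories(trajs, config, si, system)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for system {system.name!r} during "
                f"analysis: {exc}"
            ) from exc
        results[system.name] = res

        res["lag_scan"].to_csv(
            os.path.join(outdir, f"{system.name}_timescales.csv"),
            index=False)
        prof = res["profile"]
        pd.DataFrame({
            "residue": np.arange(len(prof.per_residue)),
            "helicity": prof.per_residue,
            "sem": prof.per_residue_sem,
        }).to_csv(os.path.join(outdir, f"{system.name}_helicity.csv"),
                  index=False)
        ts = msmlib.implied_timescales(res["msm"], 3)
        with open(os.path.join(outdir, f"{system.name}_summary.json"),
                  "w") as fh:
            json.dump({
                "system": system.name,
                "mean_helicity": prof.overall,
                "mean_helicity_sem": prof.overall_sem,
                "slowest_timescale_ns": None if np.isnan(ts[0])
                else float(ts[0]),
                "slowest_timescale_sem_ns":
                    float(res["bootstrap"].sem["timescales"][0]),
                "msm_lag_ns": config.msm_lag,
                "n_states": int(res["msm"].n_states),
            }, fh, indent=2)

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump({"config": cfg_dict, "config_sha256": cfg_hash,
                   "seed": config.seed}, fh, indent=2, default=str)
    return results
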