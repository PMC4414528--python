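"""High-level workflows: configuration, sweeps, phase diagrams, manifests.

These functions tie the stages together the way the reference analyses
are organized: an ensemble sweep along one parameter axis with the linear
stability prediction overlaid (periodicity and amplitude statistics vs
I, E or D), and stability phase diagrams over (I, D) or (I, E) grids.
Every run can be captured in a :class:`RunManifest` that records the full
configuration and seeds, sufficient to reproduce the outputs bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .model import TransportParams
from .simulate import EnsembleResult, SimulationConfig, run_ensemble
from .stability import dispersion

__all__ = ["FullConfig", "RunManifest", "load_config", "dump_config",
           "run_sweep", "run_phase", "ensemble_summary_frame"]

_PARAM_KEYS = {f.name for f in dc_fields(TransportParams)}
_SIM_KEYS = {"n_cells", "dt", "t_end", "noise_amplitude", "n_replicates",
             "base_seed", "snapshot_times"}


@dataclass
class FullConfig:
    """Validated full configuration: transport parameters + simulation grid."""

    params: TransportParams = field(default_factory=TransportParams)
    n_cells: int = 60
    dt: float = 1e-4
    t_end: float = 17.5
    noise_amplitude: float = 0.01
    n_replicates: int = 30
    base_seed: int = 0
    snapshot_times: tuple = ()

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            params=self.params, n_cells=self.n_cells, dt=self.dt,
            t_end=self.t_end, noise_amplitude=self.noise_amplitude,
            n_replicates=self.n_replicates, base_seed=self.base_seed,
            snapshot_times=tuple(self.snapshot_times))

    def to_dict(self) -> dict:
        d = {k: getattr(self.params, k) for k in sorted(_PARAM_KEYS)}
        for k in sorted(_SIM_KEYS):
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d


def load_config(path) -> FullConfig:
    """Read and validate a YAML/JSON config; defaults fill missing keys.

    Keys are the TransportParams field names plus the simulation fields
    (n_cells, dt, t_end, noise_amplitude, n_replicates, base_seed,
    snapshot_times).  Unknown keys, wrong types and out-of-range values
    are rejected naming the offending field.  An empty file resolves to
    the full default set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a key-value mapping")
    unknown = sorted(set(data) - _PARAM_KEYS - _SIM_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    pkw = {}
    for k in _PARAM_KEYS & set(data):
        v = data[k]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ValueError(f"config field {k} must be a number, got {v!r}")
        pkw[k] = float(v)
    skw = {}
    for k in _SIM_KEYS & set(data):
        v = data[k]
        if k == "snapshot_times":
            if not isinstance(v, (list, tuple)):
                raise ValueError("config field snapshot_times must be a list")
            skw[k] = tuple(float(t) for t in v)
        elif k in ("n_cells", "n_replicates", "base_seed"):
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"config field {k} must be an integer, got {v!r}")
            skw[k] = v
        else:
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"config field {k} must be a number, got {v!r}")
            skw[k] = float(v)
    try:
        cfg = FullConfig(params=TransportParams(**pkw), **skw)
        cfg.simulation_config()  # range checks live in the dataclasses
    except ValueError as err:
        raise ValueError(f"invalid config {path}: {err}") from None
    return cfg


def dump_config(config: FullConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: list
    outputs: list
    status: dict
    version: str = _version
    timestamp: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _new_manifest(command: str, config: FullConfig) -> RunManifest:
    return RunManifest(
        command=command, config=config.to_dict(), seeds=[], outputs=[],
        status={}, timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))


def ensemble_summary_frame(result: EnsembleResult) -> pd.DataFrame:
    """One row per (replicate, compartment) with the pattern statistics."""
    rows = []
    for r, summ in enumerate(result.summaries):
        if summ is None:
            continue
        for ps in summ:
            rows.append({
                "replicate": r, "compartment": ps.compartment,
                "n_maxima": len(ps.maxima_idx),
                "n_incipient_removed": ps.n_incipient_removed,
                "kappa": ps.kappa_sim, "amplitude": ps.amplitude,
                "mean_level": ps.mean_level,
                "avg_maxima": ps.avg_max, "avg_minima": ps.avg_min,
            })
    return pd.DataFrame(rows)


def run_sweep(config: FullConfig, axis: str, grid, manifest: RunManifest | None = None):
    """Replicate ensembles along one parameter axis with the LSA overlay.

    ``axis`` is "I", "E" or "D".  Returns ``(long_df, theory_df)``:
    ``long_df`` holds one row per (axis value, replicate, compartment,
    statistic); ``theory_df`` holds κ_theory and the patterning class per
    axis value.  Per-point integration failures are recorded in the
    manifest (when given) rather than raised.
    """
    if axis not in ("I", "E", "D"):
        raise ValueError("sweep axis must be one of I, E, D")
    if len(list(grid)) == 0:
        raise ValueError("sweep grid must be nonempty")
    manifest = manifest if manifest is not None else _new_manifest("sweep", config)
    long_rows, theory_rows = [], []
    for value in grid:
        params = config.params.with_(**{axis: float(value)})
        sim_cfg = config.simulation_config()
        sim_cfg.params = params
        result = run_ensemble(sim_cfg)
        manifest.seeds.extend(result.seeds)
        for rep, msg in result.failures:
            manifest.status[f"{axis}={value}/replicate{rep}"] = f"failed: {msg}"
        frame = ensemble_summary_frame(result)
        stat_cols = [c for c in frame.columns if c not in ("replicate", "compartment")]
        melted = frame.melt(id_vars=["replicate", "compartment"],
                            value_vars=stat_cols, var_name="statistic")
        melted.insert(0, "axis_value", float(value))
        long_rows.append(melted)
        rep_th = dispersion(params, config.n_cells)
        theory_rows.append({
            "axis_value": float(value), "kappa_theory": rep_th.kappa_theory,
            "is_patterning": rep_th.is_patterning,
            "max_growth": float(rep_th.growth_rates[rep_th.fastest_mode]),
            "q_star": rep_th.fastest_mode,
        })
        manifest.status.setdefault(f"{axis}={value}", "ok")
    long_df = pd.concat(long_rows, ignore_index=True)
    theory_df = pd.DataFrame(theory_rows)
    return long_df, theory_df


def run_phase(config: FullConfig, axes, grid1, grid2):
    """Stability phase diagram over a 2-d parameter grid.

    ``axes`` is ("I", "D") or ("I", "E").  Returns a tidy DataFrame with
    one row per grid point: I, D_or_E, max_growth, q_star, kappa,
    is_patterning.
    """
    ax1, ax2 = axes
    if ax1 != "I" or ax2 not in ("D", "E"):
        raise ValueError("phase axes must be ('I', 'D') or ('I', 'E')")
    rows = []
    for v1 in grid1:
        for v2 in grid2:
            p = config.params.with_(**{ax1: float(v1), ax2: float(v2)})
            rep = dispersion(p, config.n_cells)
            rows.append({
                "I": float(v1), "D_or_E": float(v2),
                "max_growth": float(rep.growth_rates[rep.fastest_mode]),
                "q_star": rep.fastest_mode, "kappa": rep.kappa_theory,
                "is_patterning": rep.is_patterning,
            })
    return pd.DataFrame(rows)
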