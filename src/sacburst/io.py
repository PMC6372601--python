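"""Configuration files, result serialization and logging helpers.

Configs are flat YAML key-value files, one key per model parameter plus run
settings; unknown keys are rejected, missing keys fall back to defaults
(logged). Gridded results go to delimited text with headers; scalar records
(fits, reports) to YAML. Numeric output uses 9 significant digits, enough
for a lossless round trip at the stated precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .bursts import BurstConfig, SqrtLawFit
from .integrate import StimulusProtocol, Trajectory
from .params import ModelParameters

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_table",
    "write_record",
    "MISSING",
]

logger = logging.getLogger(__name__)

#: sentinel token for missing heat-map cells (never serialized as 0)
MISSING = "NA"

_RUN_KEYS = {"T", "dt", "seed", "stride", "sigma"}
_BURST_KEYS = {"calcium_threshold", "min_duration"}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of model parameters and run settings."""

    params: ModelParameters
    T: float = 600_000.0
    dt: float = 0.05
    seed: int = 0
    stride: int | None = None
    burst: BurstConfig = field(default_factory=BurstConfig)

    def effective_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = dict(self.params.to_dict())
        d.update(T=self.T, dt=self.dt, seed=self.seed)
        if self.stride is not None:
            d["stride"] = self.stride
        d.update(
            calcium_threshold=self.burst.calcium_threshold,
            min_duration=self.burst.min_duration,
        )
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys raise, absent keys use defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    param_fields = {f.name for f in dataclasses.fields(ModelParameters)}
    known = param_fields | _RUN_KEYS | _BURST_KEYS
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    missing = param_fields - set(raw)
    if missing:
        logger.info("config %s: %d parameter(s) filled from defaults", path, len(missing))
    params = ModelParameters.from_dict({k: raw[k] for k in param_fields & set(raw)})
    burst_kwargs = {k: float(raw[k]) for k in _BURST_KEYS & set(raw)}
    dt = float(raw.get("dt", 0.05))
    if not 0.0 < dt <= 0.5:
        raise ValueError(f"config key dt={dt} outside (0, 0.5] ms")
    return RunConfig(
        params=params,
        T=float(raw.get("T", 600_000.0)),
        dt=dt,
        seed=int(raw.get("seed", 0)),
        stride=int(raw["stride"]) if "stride" in raw else None,
        burst=BurstConfig(**burst_kwargs),
    )


def write_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective config so that a reload reproduces it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.effective_dict(), sort_keys=True, default_flow_style=False)
    )


_TRAJ_HEADER = "t_ms\tV_mV\tN\tC_nM\tS\tR"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV plus a YAML metadata sidecar (.meta.yaml)."""
    path = Path(path)
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t", header=_TRAJ_HEADER, comments="")
    meta = {
        "dt": traj.dt,
        "seed": traj.seed,
        "stride": traj.stride,
        "n_clamps": traj.n_clamps,
        "params": traj.params.to_dict(),
        "protocol": [list(s) for s in traj.protocol.segments],
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_trajectory(path: str | Path) -> Trajectory:
    """Reload a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    return Trajectory(
        times=data[:, 0],
        states=data[:, 1:],
        params=ModelParameters.from_dict(meta["params"]),
        dt=float(meta["dt"]),
        seed=int(meta["seed"]),
        protocol=StimulusProtocol(tuple(tuple(s) for s in meta["protocol"])),
        stride=int(meta["stride"]),
        n_clamps=int(meta["n_clamps"]),
    )


def write_table(
    array: np.ndarray,
    path: str | Path,
    header: str,
    row_labels: np.ndarray | None = None,
) -> None:
    """Delimited-text table with header; NaN cells become the NA sentinel."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(array, dtype=float))
    lines = [header]
    for i in range(arr.shape[0]):
        cells = [MISSING if np.isnan(x) else f"{x:.9g}" for x in arr[i]]
        if row_labels is not None:
            cells.insert(0, f"{row_labels[i]:.9g}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def write_record(record: dict[str, Any] | SqrtLawFit, path: str | Path) -> None:
    """Structured-text (YAML) record for scalar results and fits."""
    if isinstance(record, SqrtLawFit):
        record = {
            "K_s_pA_half": record.K,
            "K_stderr": record.K_stderr,
            "K_ci95": list(record.K_ci95),
            "I_c_pA": record.I_c,
            "I_c_stderr": record.I_c_stderr,
            "residual_norm": record.residual_norm,
            "form": record.form,
            "n_points": record.n_points,
        }
    clean = {}
    for k, v in record.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=False))
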