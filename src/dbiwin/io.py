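"""Tabular readers/writers, run configuration and serialization plumbing.

All on-disk formats are plain text: tab- (or comma-) separated tables with
a header row for time-series and per-block results, YAML for run
configuration, JSON for structured sidecars (covariance matrices, plans,
logs).  Writers are atomic: output lands under the final name only after
a complete temporary file is renamed over it.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import InferenceRun
from .window_optimizer import WindowPlan

__all__ = [
    "RunConfig",
    "read_series",
    "write_series",
    "write_run",
    "write_plan",
    "atomic_write_text",
]

#: relative tolerance on successive time steps for the uniform-grid check
GRID_RTOL = 1e-6


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temporary file + rename (no partial files)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_series(path: str | Path) -> tuple[pd.DataFrame, float]:
    """Read a uniform-grid time-series table; returns (table, step h).

    The delimiter is auto-detected among tab and comma; the first column
    must be a monotone, uniformly spaced time axis.  A gap or irregular
    step raises with the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.dropna(axis=1, how="all")  # delimiter sniffing can add ghosts
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one signal")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError(f"{path}: too few rows")
    dt = np.diff(t)
    h = float(np.median(dt))
    if h <= 0:
        raise ValueError(f"{path}: time column not increasing")
    bad = np.nonzero(np.abs(dt - h) > GRID_RTOL * max(abs(h), 1.0))[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise ValueError(
            f"{path}: non-uniform time grid at data row {row} "
            f"(step {dt[bad[0]]:.6g}, expected {h:.6g})"
        )
    return df, h


def write_series(
    path: str | Path, time: np.ndarray, columns: dict[str, np.ndarray]
) -> None:
    """Write a time-series table as tab-separated text with a header row."""
    df = pd.DataFrame({"time": np.asarray(time), **columns})
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.10g"))


def write_run(
    path: str | Path, run: InferenceRun, sigma_sidecar: str | Path | None = None
) -> None:
    """Serialize an inference run as a per-block table (+ optional sidecar).

    The table holds block_time, every parameter c (labelled by oscillator
    and base function), the noise diagonal and Q_Sigma.  The sidecar, if
    requested, stores the per-block covariance matrices as JSON.
    """
    model = run.settings.model
    labels = model.term_labels()
    cols: dict[str, np.ndarray] = {}
    C = run.parameter_series()
    for osc in (1, 2):
        for li, lab in enumerate(labels):
            cols[f"c{osc}:{lab}"] = C[:, model.global_index(osc, li)]
    E = run.noise_series()
    cols["sqrtE11"] = E[:, 0]
    cols["sqrtE22"] = E[:, 1]
    cols["q_sigma"] = run.q_sigma
    write_series(path, run.block_times, cols)
    if sigma_sidecar is not None:
        payload = {
            "t_w": run.settings.t_w,
            "p_w": run.settings.p_w,
            "order": run.settings.order,
            "block_times": run.block_times.tolist(),
            "sigma": [s.Sigma.tolist() for s in run.states],
        }
        atomic_write_text(sigma_sidecar, json.dumps(payload))


def write_plan(path: str | Path, plan: WindowPlan) -> None:
    """Serialize a window plan as key-value text (spectra inline as JSON)."""
    lines = [
        f"f_max\t{plan.f_max:.8g}",
        f"T_min\t{plan.T_min:.8g}",
        f"t_w_opt\t{plan.t_w_opt:.8g}",
        f"p_w_opt\t{plan.p_w_opt:.8g}",
        f"initial_t_w\t{plan.initial_t_w:.8g}",
    ]
    if plan.spectra:
        spectra = {k: np.asarray(v).tolist() for k, v in plan.spectra.items()}
        lines.append("spectra\t" + json.dumps(spectra))
    atomic_write_text(path, "\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips losslessly via YAML."""

    input_path: str = ""
    output_dir: str = "dbiwin_out"
    seed: int = 0
    # simulation stage (used when input_path is empty)
    simulate: str = "sine"  # fixture kind, or "phase"/"poincare" for raw phases
    duration: float = 1200.0
    h: float = 0.01
    # extraction stage
    band1: tuple[float, float] = (0.145, 0.6)
    band2: tuple[float, float] = (0.6, 2.0)
    transform_phases: bool = True
    # optimizer stage
    initial_t_w: float | None = None
    order: int = 2
    significance: float = 5.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["band1"] = list(d["band1"])
        d["band2"] = list(d["band2"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        for key in ("band1", "band2"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        atomic_write_text(path, self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global one (stable, < 2**31)."""
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))
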