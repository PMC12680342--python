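"""Pseudo-experimental dataset generation and I/O.

Datasets are tidy tables of records ``(experiment, observable, time, value,
sigma)`` covering one or more experiments; ``sigma`` is the measurement
standard deviation used to weight the calibration objective.  The synthetic
generator samples model trajectories at the design's grids and corrupts them
with Gaussian noise — absolute, proportional to the noise-free signal, or
mixed — emulating pseudo-experimental benchmark data with controlled noise
levels (e.g. 0/5/10% proportional).

On-disk format: CSV with columns ``experiment, observable, time, value,
sigma`` plus a JSON sidecar (``<path>.meta.json``) holding provenance
(nominal parameters, noise model, seed) for synthetic data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import ExperimentDesign, ModelSpec
from .simulator import simulate

__all__ = ["NoiseModel", "Dataset", "generate_dataset", "write_dataset",
           "read_dataset", "split_dataset", "DatasetParseError"]

COLUMNS = ["experiment", "observable", "time", "value", "sigma"]


class DatasetParseError(ValueError):
    """Raised when a dataset file has malformed rows."""


@dataclass
class NoiseModel:
    """Gaussian measurement-noise description.

    ``kind``: ``absolute`` (sigma = level), ``proportional`` (sigma =
    level * |signal|, floored), or ``mixed`` (sigma = sqrt(abs^2 + prop^2)
    with ``level=(abs_level, prop_level)``).  ``floor`` is the minimum
    standard deviation; ``None`` resolves to ``1e-6 * max|y|`` over the
    design at generation time so extinction points never get zero weight.
    """

    kind: str = "proportional"
    level: object = 0.05
    floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "proportional", "mixed"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "proportional":
            lvl = float(self.level)
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("proportional noise level must lie in [0, 1]")
        if self.floor is not None and self.floor <= 0:
            raise ValueError("noise floor must be positive")

    def sigma(self, y_true: np.ndarray, floor: float) -> np.ndarray:
        y_true = np.asarray(y_true, dtype=float)
        if self.kind == "absolute":
            s = float(self.level) * np.ones_like(y_true)
        elif self.kind == "proportional":
            s = float(self.level) * np.abs(y_true)
        else:
            a, p = self.level
            s = np.sqrt(float(a) ** 2 + (float(p) * np.abs(y_true)) ** 2)
        return np.maximum(s, floor)

    @property
    def is_null(self) -> bool:
        """True when the model draws no noise (level exactly zero)."""
        if self.kind == "mixed":
            a, p = self.level
            return float(a) == 0.0 and float(p) == 0.0
        return float(self.level) == 0.0


@dataclass
class Dataset:
    """Tidy multi-experiment measurement table with provenance."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset records missing columns: {missing}")
        self.records = df[COLUMNS].reset_index(drop=True)
        if len(self.records) and not (self.records["sigma"] > 0).all():
            raise ValueError("every record must have sigma > 0")
        self.records = self.records.sort_values(
            ["experiment", "observable", "time"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records.equals(other.records)

    @property
    def n_e(self) -> int:
        return self.records["experiment"].nunique()

    @property
    def experiments(self) -> list:
        return list(dict.fromkeys(self.records["experiment"]))

    def n_obs(self, experiment) -> int:
        sub = self.records[self.records["experiment"] == experiment]
        return sub["observable"].nunique()

    def n_samples(self, experiment, observable) -> int:
        sub = self.records[
            (self.records["experiment"] == experiment)
            & (self.records["observable"] == observable)
        ]
        return len(sub)

    def subset(self, experiment_ids: Sequence) -> "Dataset":
        mask = self.records["experiment"].isin(list(experiment_ids))
        return Dataset(self.records[mask].copy(), provenance=dict(self.provenance))


def generate_dataset(
    model: ModelSpec,
    theta_nominal: np.ndarray,
    designs: Sequence[ExperimentDesign],
    noise: NoiseModel,
    seed: int,
    truncate_at_zero: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Dataset:
    """Simulate every design at the nominal parameters and add Gaussian noise.

    ``sigma`` is computed from the noise-free signal (not the noisy draw), so
    the stored weights match the generating process exactly.  Negative noisy
    abundances are kept by default; ``truncate_at_zero`` clips them, at the
    cost of biasing the Gaussian error model.
    """
    rng = np.random.default_rng(seed)
    theta_nominal = np.asarray(theta_nominal, dtype=float)

    # First pass: noise-free signals, to resolve the default floor.
    signals = {}
    y_max = 0.0
    for design in designs:
        traj = simulate(model, theta_nominal, design, rtol=rtol, atol=atol)
        if not traj.ok:
            raise RuntimeError(
                f"nominal simulation failed for experiment "
                f"{design.experiment_id!r} (status={traj.status}, "
                f"t_stop={traj.t_stop:.4g}); cannot generate data"
            )
        per_obs = {}
        for o_idx, name in enumerate(design.observation_map.observable_names):
            times = design.sampling_times.get(name, np.empty(0))
            y = np.array([
                design.observation_map(traj.state_at(t), t)[o_idx] for t in times
            ])
            per_obs[name] = (times, y)
            if y.size:
                y_max = max(y_max, float(np.max(np.abs(y))))
        signals[design.experiment_id] = per_obs

    floor = noise.floor if noise.floor is not None else max(1e-6 * y_max, 1e-12)

    rows = []
    for design in designs:
        for name, (times, y) in signals[design.experiment_id].items():
            sig = noise.sigma(y, floor)
            # sigma is floored for weighting, but a zero noise *level* means
            # the recorded values are exactly the noise-free signal
            ym = y + rng.normal(0.0, sig) if (len(y) and not noise.is_null) else y
            if truncate_at_zero:
                ym = np.maximum(ym, 0.0)
            for t, v, s in zip(times, ym, sig):
                rows.append((design.experiment_id, name, float(t), float(v), float(s)))

    df = pd.DataFrame(rows, columns=COLUMNS)
    provenance = {
        "synthetic": True,
        "model_kind": model.kind,
        "n_x": model.n_x,
        "theta_nominal": theta_nominal.tolist(),
        "noise": {"kind": noise.kind, "level": noise.level, "floor": floor},
        "seed": int(seed),
        "truncate_at_zero": bool(truncate_at_zero),
    }
    return Dataset(df, provenance=provenance)


def write_dataset(dataset: Dataset, path: str) -> None:
    """Write the records CSV plus a provenance sidecar JSON."""
    dataset.records.to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump(dataset.provenance, fh, indent=2, sort_keys=True)


def read_dataset(path: str) -> Dataset:
    """Read a dataset CSV (and its sidecar, if present), validating rows."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise DatasetParseError(f"{path}: missing columns {missing} in header")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "value", "sigma"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based numbering
            raise DatasetParseError(
                f"{path}: non-numeric {col!r} at line {int(bad[0]) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    provenance = {}
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as fh:
            provenance = json.load(fh)
    return Dataset(df, provenance=provenance)


def split_dataset(dataset: Dataset, held_out_experiments: Sequence) -> dict:
    """Partition into training/validation by experiment id (disjoint, lossless)."""
    held = list(held_out_experiments)
    known = set(dataset.records["experiment"])
    unknown = [e for e in held if e not in known]
    if unknown:
        raise KeyError(f"unknown experiment ids: {unknown}")
    mask = dataset.records["experiment"].isin(held)
    return {
        "training": Dataset(dataset.records[~mask].copy(),
                            provenance=dict(dataset.provenance)),
        "validation": Dataset(dataset.records[mask].copy(),
                              provenance=dict(dataset.provenance)),
    }


def _sidecar(path: str) -> str:
    return str(path) + ".meta.json"
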