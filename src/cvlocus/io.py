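"""File formats: sweep CSV, run configuration, result serialization.

Sweep CSV dialect (header required, sweep index 0-based):

    sweep,time_s,epoch,amplitude_mV[,rin_mohm,vm_mv]

``epoch`` is one of ``baseline``, ``post`` or ``induction``; induction rows
are retained on read but excluded from analysis epochs.  Writing is
deterministic: fixed column order and 6-significant-digit formatting, so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .quantal import QuantalParams
from .simulate import (
    ExperimentDesign,
    Perturbation,
    PlasticityScenario,
    SweepSeries,
)

__all__ = [
    "FormatError",
    "read_sweeps",
    "write_sweeps",
    "RunConfig",
    "write_sidecar",
]

_REQUIRED_COLUMNS = ("sweep", "time_s", "epoch", "amplitude_mV")
_EPOCHS = {"baseline", "post", "induction"}


class FormatError(ValueError):
    """A sweep or config file violates the documented schema."""


def read_sweeps(path: Union[str, Path]) -> SweepSeries:
    """Read a sweep series from the CSV dialect above."""
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    bad = set(df["epoch"].astype(str)) - _EPOCHS
    if bad:
        raise FormatError(f"unknown epoch labels {sorted(bad)} in {path}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise FormatError(f"time_s must be strictly increasing in {path}")
    kwargs = {}
    for col, attr in (("rin_mohm", "rin_mohm"), ("vm_mv", "vm_mv")):
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    return SweepSeries(
        amplitudes=df["amplitude_mV"].to_numpy(dtype=float),
        times=times,
        epoch_labels=df["epoch"].astype(str).to_numpy(dtype=object),
        **kwargs,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_sweeps(series: SweepSeries, path: Union[str, Path]) -> None:
    """Write a sweep series to CSV, deterministically formatted."""
    cols = ["sweep", "time_s", "epoch", "amplitude_mV"]
    data = {
        "sweep": [str(i) for i in range(len(series))],
        "time_s": [_fmt(t) for t in series.times],
        "epoch": [str(e) for e in series.epoch_labels],
        "amplitude_mV": [_fmt(a) for a in series.amplitudes],
    }
    if series.rin_mohm is not None:
        cols.append("rin_mohm")
        data["rin_mohm"] = [_fmt(v) for v in series.rin_mohm]
    if series.vm_mv is not None:
        cols.append("vm_mv")
        data["vm_mv"] = [_fmt(v) for v in series.vm_mv]
    lines = [",".join(cols)]
    for i in range(len(series)):
        lines.append(",".join(data[c][i] for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class RunConfig:
    """Complete run configuration; round-trips losslessly through YAML/JSON."""

    design: ExperimentDesign = dataclasses.field(default_factory=ExperimentDesign)
    baseline_params: QuantalParams = dataclasses.field(
        default_factory=lambda: QuantalParams(5, 0.55, 0.35, 0.1)
    )
    post_params: QuantalParams = dataclasses.field(
        default_factory=lambda: QuantalParams(5, 0.4, 0.35, 0.1)
    )
    perturbation: Perturbation = dataclasses.field(default_factory=Perturbation)
    correct_noise: bool = False
    bin_sweeps: int = 20
    delta_post_deg: float = 15.0
    z_threshold: float = 4.0
    seed: int = 0
    output: Optional[str] = None

    @property
    def scenario(self) -> PlasticityScenario:
        return PlasticityScenario(self.baseline_params, self.post_params)

    def to_dict(self) -> dict:
        return {
            "design": dataclasses.asdict(self.design),
            "baseline_params": dataclasses.asdict(self.baseline_params),
            "post_params": dataclasses.asdict(self.post_params),
            "perturbation": dataclasses.asdict(self.perturbation),
            "correct_noise": self.correct_noise,
            "bin_sweeps": self.bin_sweeps,
            "delta_post_deg": self.delta_post_deg,
            "z_threshold": self.z_threshold,
            "seed": self.seed,
            "output": self.output,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "design" in kwargs:
            kwargs["design"] = ExperimentDesign(**kwargs["design"])
        if "baseline_params" in kwargs:
            kwargs["baseline_params"] = QuantalParams(**kwargs["baseline_params"])
        if "post_params" in kwargs:
            kwargs["post_params"] = QuantalParams(**kwargs["post_params"])
        if "perturbation" in kwargs:
            kwargs["perturbation"] = Perturbation(**kwargs["perturbation"])
        return cls(**kwargs)

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise FormatError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)


def write_sidecar(config: RunConfig, path: Union[str, Path]) -> None:
    """Write the run parameters next to a data file for provenance."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
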