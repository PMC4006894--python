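"""Reading and writing growth tables, configuration and run manifests."""

from __future__ import annotations

import hashlib
import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["read_growth_table", "write_growth_table", "RunManifest"]

_C_TO_K = 273.15


def read_growth_table(path, units: str = "K") -> pd.DataFrame:
    """Read a delimited growth table into standardised records.

    Expects a header with columns ``strain_id``, ``temperature`` (or
    ``temperature_K``/``temperature_C``) and ``rate`` (or ``rate_obs``);
    ``units`` ("K" or "C") applies to a bare ``temperature`` column.
    Temperatures are converted to Kelvin, rates must be non-negative and
    (strain, temperature) pairs unique; violations raise errors naming the
    offending file lines (header = line 1).
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path}: file contains no records")
    cols = {c.lower(): c for c in df.columns}

    def pick(*options):
        for o in options:
            if o in cols:
                return cols[o]
        return None

    sid_col = pick("strain_id", "strain")
    rate_col = pick("rate", "rate_obs", "growth_rate")
    t_col = pick("temperature_k", "temperature_c", "temperature", "temp")
    missing = [label for label, c in
               [("strain_id", sid_col), ("temperature", t_col), ("rate", rate_col)]
               if c is None]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")

    T = pd.to_numeric(df[t_col], errors="coerce")
    rate = pd.to_numeric(df[rate_col], errors="coerce")
    for label, series in (("temperature", T), ("rate", rate)):
        bad = series.index[series.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"{path}: unparseable {label} values at lines {lines}")
    if t_col.lower() == "temperature_c" or (t_col.lower() in ("temperature", "temp")
                                            and units.upper().startswith("C")):
        T = T + _C_TO_K
    neg = rate.index[rate < 0]
    if len(neg):
        lines = ", ".join(str(i + 2) for i in neg[:5])
        raise ValueError(f"{path}: negative rates at lines {lines}")

    out = pd.DataFrame({"strain_id": df[sid_col].astype(str),
                        "temperature_K": T.astype(float),
                        "rate_obs": rate.astype(float)})
    if (g := pick("group", "thermal_group")) is not None:
        out["group"] = df[g].astype(str)
    dup = out.duplicated(["strain_id", "temperature_K"])
    if dup.any():
        lines = ", ".join(str(i + 2) for i in out.index[dup][:5])
        raise ValueError(f"{path}: duplicate (strain, temperature) rows at "
                         f"lines {lines}")
    counts = out.groupby("strain_id").size()
    out.attrs["records_per_strain"] = counts.to_dict()
    return out


def write_growth_table(records: pd.DataFrame, path) -> None:
    cols = [c for c in ("strain_id", "group", "temperature_K", "rate_obs",
                        "rate_std") if c in records.columns]
    records[cols].to_csv(path, index=False)


def _checksum(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of a pipeline stage: inputs, seed, outputs with checksums."""

    stage: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    outcome: str = "pending"
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add_input(self, path) -> None:
        p = pathlib.Path(path)
        self.inputs[str(p)] = _checksum(p)

    def add_output(self, path) -> None:
        p = pathlib.Path(path)
        self.outputs[str(p)] = _checksum(p)

    def finish(self, outcome: str = "success") -> None:
        self.outcome = outcome
        self.finished = time.time()

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "stage": self.stage,
            "seed": self.seed,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "version": __version__,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "outcome": self.outcome,
            "started": self.started,
            "finished": self.finished,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
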