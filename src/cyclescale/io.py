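"""Reading time series and writing result records.

Input signals are plain delimited text (CSV/TSV): one column per channel, an
optional single header row (auto-detected), uniformly sampled. The sampling
rate is never inferred from the file — it must be supplied by the caller,
because a bare column of numbers carries no time base.

Results are written as JSON. Floats survive the round trip exactly because
``json`` serializes them with ``repr``, which is shortest-exact for IEEE-754
doubles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InputError, ValidationError

__all__ = ["TimeSeries", "ResultRecord", "read_timeseries", "write_result", "read_result"]


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values
        Signal samples (arbitrary units). At least two samples, all finite.
    fs
        Sampling rate in Hz, strictly positive.
    label
        Free-text description (channel name, subject id, ...).
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                f"time series must be 1-D with length >= 2, got shape {self.values.shape}"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(f"non-finite value at sample row {row} (1-based)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.values.size / self.fs


@dataclass
class ResultRecord:
    """Serializable record of one analysis run.

    ``parameters`` holds every knob that influenced the run, ``derived`` the
    scalar outputs (beta, rho, sigma2, eigenvalues, ...). The JSON round trip
    is lossless for all numeric fields.
    """

    parameters: dict[str, Any] = field(default_factory=dict)
    derived: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    input_description: str = ""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ResultRecord":
        return cls(
            parameters=dict(d.get("parameters", {})),
            derived=dict(d.get("derived", {})),
            seed=d.get("seed"),
            input_description=d.get("input_description", ""),
        )


def _jsonify(obj: Any) -> Any:
    """Coerce numpy scalars/arrays to plain Python for exact JSON output."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _looks_like_header(fields: list[str]) -> bool:
    for f in fields:
        f = f.strip()
        if not f:
            continue
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_timeseries(
    path: str | Path,
    column: int | str = 0,
    delimiter: str = ",",
    fs: float = 1.0,
    label: str | None = None,
) -> TimeSeries:
    """Read one column of a delimited text file as a :class:`TimeSeries`.

    A single header row is auto-detected (any non-numeric field in the first
    line). ``column`` selects by integer position or, when a header is
    present, by name. Row order is preserved; nothing is dropped. Any
    non-finite value (NaN, inf, empty cell) raises :class:`ValidationError`
    naming the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise InputError(f"empty file: {path}")
    has_header = _looks_like_header(first.rstrip("\n").split(delimiter))
    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if has_header else None,
        skip_blank_lines=False,
    )
    if isinstance(column, str):
        if not has_header:
            raise InputError(f"file has no header row; cannot select column {column!r}")
        if column not in df.columns:
            raise InputError(f"column {column!r} not found; available: {list(df.columns)}")
        series = df[column]
    else:
        if column < 0 or column >= df.shape[1]:
            raise InputError(f"column index {column} out of range for {df.shape[1]} columns")
        series = df.iloc[:, column]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=np.float64)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(f"non-finite value in column {column!r} at data row {row} (1-based)")
    if label is None:
        label = str(column) if isinstance(column, str) else f"{path.name}[{column}]"
    return TimeSeries(values=values, fs=fs, label=label)


def write_result(record: ResultRecord, path: str | Path) -> None:
    """Write a :class:`ResultRecord` as JSON; read-back is numerically exact."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(_jsonify(record.to_dict()), fh, indent=2, allow_nan=False)
            fh.write("\n")
    except OSError as exc:
        raise InputError(f"cannot write result to {path}: {exc}") from exc


def read_result(path: str | Path) -> ResultRecord:
    """Read back a JSON result record written by :func:`write_result`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        return ResultRecord.from_dict(json.load(fh))
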