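"""Reading, validating and writing particle-size and protein-quant tables.

Two plain CSV dialects carry Coulter-counter-style granule size data:

* binned:  header ``bin_lower_um,bin_upper_um,count`` — one row per
  diameter bin.  Bins are half-open ``[lower, upper)``, strictly
  increasing and non-overlapping (gaps are permitted).
* raw:     header ``diameter_um`` — one row per particle.

Sample metadata (sample id, analyzed/total suspension volume, fresh
weight) travels as ``# key=value`` comment lines before the header.

Protein quantification tables use header
``accession,pd_1..pd_n,ctrl_1..ctrl_n[,ratio,p_value,p_adjusted]`` with an
equal number of pulldown and control replicate columns (three in the
study design); alternatively a table may carry only precomputed
``ratio``/``p_value`` columns, as when transcribing a printed table.

All diameters are micrometres; there is no unit-conversion layer.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GranulekitError",
    "FormatError",
    "ValidationError",
    "ParticleSizeData",
    "ProteinQuantTable",
    "read_size_csv",
    "write_size_csv",
    "read_quant_csv",
    "write_quant_csv",
]


class GranulekitError(Exception):
    """Base class for all granulekit errors."""


class FormatError(GranulekitError, ValueError):
    """A file could not be parsed in the documented CSV dialect."""


class ValidationError(GranulekitError, ValueError):
    """Parsed data violate a domain invariant."""


# metadata keys parsed to float when present
_NUMERIC_META = ("analyzed_volume_ml", "total_volume_ml", "fresh_weight_mg")


@dataclass(frozen=True)
class ParticleSizeData:
    """A particle-size dataset: either binned counts or raw diameters.

    The two representations are mutually exclusive.  Binned data consist
    of half-open ``[lower, upper)`` diameter bins (µm) with non-negative
    integer particle counts; raw data is a flat list of per-particle
    diameters (µm).
    """

    bin_lower: np.ndarray | None = None
    bin_upper: np.ndarray | None = None
    count: np.ndarray | None = None
    raw_diameters: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        binned = self.bin_lower is not None
        raw = self.raw_diameters is not None
        if binned == raw:
            raise ValidationError(
                "exactly one of binned and raw representations must be set"
            )
        if binned:
            lo = np.asarray(self.bin_lower, dtype=float)
            up = np.asarray(self.bin_upper, dtype=float)
            ct = np.asarray(self.count, dtype=float)
            if not (lo.shape == up.shape == ct.shape) or lo.ndim != 1:
                raise ValidationError("bin arrays must be 1-D and equal length")
            if lo.size == 0:
                raise ValidationError("binned data must contain at least one bin")
            if np.any(lo <= 0):
                raise ValidationError("bin edges must be positive diameters")
            if np.any(up <= lo):
                bad = int(np.flatnonzero(up <= lo)[0])
                raise FormatError(f"bin upper <= lower at row {bad}")
            if np.any(lo[1:] < up[:-1]):
                bad = int(np.flatnonzero(lo[1:] < up[:-1])[0]) + 1
                raise FormatError(f"overlapping bins at row {bad}")
            if np.any(ct < 0):
                raise ValidationError("negative counts are not allowed")
            if np.any(ct != np.round(ct)):
                raise ValidationError("counts must be integers")
            if ct.sum() < 1:
                raise ValidationError("total count must be >= 1")
            object.__setattr__(self, "bin_lower", lo)
            object.__setattr__(self, "bin_upper", up)
            object.__setattr__(self, "count", ct.astype(np.int64))
        else:
            d = np.asarray(self.raw_diameters, dtype=float)
            if d.ndim != 1 or d.size == 0:
                raise ValidationError("raw data must be a non-empty 1-D array")
            if np.any(~np.isfinite(d)) or np.any(d <= 0):
                raise ValidationError("all diameters must be finite and > 0")
            object.__setattr__(self, "raw_diameters", d)

    @property
    def is_binned(self) -> bool:
        return self.bin_lower is not None

    @property
    def total_count(self) -> int:
        if self.is_binned:
            return int(self.count.sum())
        return int(self.raw_diameters.size)


def _parse_meta(lines: Iterable[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        key = key.strip()
        value = value.strip()
        if key in _NUMERIC_META:
            try:
                meta[key] = float(value)
            except ValueError as exc:
                raise FormatError(f"metadata {key!r} is not numeric: {value!r}") from exc
        else:
            meta[key] = value
    return meta


def _split_comments(path: str | Path) -> tuple[dict, str]:
    text = Path(path).read_text(encoding="utf-8")
    comments = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    return _parse_meta(comments), body


def read_size_csv(path: str | Path, dialect: str | None = None) -> ParticleSizeData:
    """Read a particle-size CSV, auto-detecting the dialect from the header.

    Parameters
    ----------
    path
        CSV file in one of the two documented dialects.
    dialect
        ``"binned"``, ``"raw"`` or ``None`` (detect from the header).
    """
    meta, body = _split_comments(path)
    try:
        frame = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip() for c in frame.columns]
    frame.columns = cols
    if dialect is None:
        dialect = "raw" if cols == ["diameter_um"] else "binned"
    if dialect == "raw":
        if "diameter_um" not in cols:
            raise FormatError(f"{path}: raw dialect requires a 'diameter_um' column")
        return ParticleSizeData(
            raw_diameters=frame["diameter_um"].to_numpy(float), meta=meta
        )
    if dialect == "binned":
        required = ("bin_lower_um", "bin_upper_um", "count")
        if any(c not in cols for c in required):
            raise FormatError(
                f"{path}: binned dialect requires columns {', '.join(required)}"
            )
        return ParticleSizeData(
            bin_lower=frame["bin_lower_um"].to_numpy(float),
            bin_upper=frame["bin_upper_um"].to_numpy(float),
            count=frame["count"].to_numpy(float),
            meta=meta,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_size_csv(data: ParticleSizeData, path: str | Path) -> None:
    """Write ``data`` in its native dialect, metadata as ``# key=value``."""
    lines = [f"# {k}={v}" for k, v in sorted(data.meta.items())]
    if data.is_binned:
        lines.append("bin_lower_um,bin_upper_um,count")
        for lo, up, ct in zip(data.bin_lower, data.bin_upper, data.count):
            lines.append(f"{float(lo)!r},{float(up)!r},{int(ct)}")
    else:
        lines.append("diameter_um")
        lines.extend(repr(float(d)) for d in data.raw_diameters)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_PD_RE = re.compile(r"^pd_(\d+)$")
_CTRL_RE = re.compile(r"^ctrl_(\d+)$")


@dataclass
class ProteinQuantTable:
    """Per-accession replicate abundances for pulldown vs. control.

    Wraps a DataFrame with an ``accession`` column, matched
    ``pd_i``/``ctrl_i`` replicate abundance columns (all positive, no
    missing values — imputation is out of scope), and optional
    ``ratio``/``p_value``/``p_adjusted`` columns.
    """

    frame: pd.DataFrame
    n_replicates: int = 0

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        if "accession" not in frame.columns:
            raise ValidationError("quant table requires an 'accession' column")
        pd_cols = sorted(
            (c for c in frame.columns if _PD_RE.match(c)),
            key=lambda c: int(_PD_RE.match(c).group(1)),
        )
        ctrl_cols = sorted(
            (c for c in frame.columns if _CTRL_RE.match(c)),
            key=lambda c: int(_CTRL_RE.match(c).group(1)),
        )
        if len(pd_cols) != len(ctrl_cols):
            raise ValidationError(
                f"unequal replicate counts: {len(pd_cols)} pulldown vs "
                f"{len(ctrl_cols)} control columns"
            )
        self.n_replicates = len(pd_cols)
        if self.n_replicates:
            abund = frame[pd_cols + ctrl_cols].to_numpy(float)
            if np.any(~np.isfinite(abund)):
                raise ValidationError("missing or non-finite abundance values")
            if np.any(abund <= 0):
                raise ValidationError("abundances must be positive")
        elif "ratio" not in frame.columns:
            raise ValidationError(
                "quant table needs replicate abundances or a precomputed ratio column"
            )
        if "ratio" in frame.columns and np.any(frame["ratio"].to_numpy(float) <= 0):
            raise ValidationError("ratios must be positive")
        for col in ("p_value", "p_adjusted"):
            if col in frame.columns:
                p = frame[col].to_numpy(float)
                if np.any((p < 0) | (p > 1)):
                    raise ValidationError(f"{col} outside [0, 1]")
        self.frame = frame
        self._pd_cols = pd_cols
        self._ctrl_cols = ctrl_cols

    def pulldown_matrix(self) -> np.ndarray:
        """(n_proteins, n_replicates) pulldown abundances."""
        return self.frame[self._pd_cols].to_numpy(float)

    def control_matrix(self) -> np.ndarray:
        """(n_proteins, n_replicates) control abundances."""
        return self.frame[self._ctrl_cols].to_numpy(float)

    def __len__(self) -> int:
        return len(self.frame)


def read_quant_csv(path: str | Path) -> ProteinQuantTable:
    """Read a protein quantification CSV into a validated table."""
    meta, body = _split_comments(path)
    del meta  # metadata is accepted but not used for quant tables
    try:
        frame = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    frame.columns = [c.strip() for c in frame.columns]
    return ProteinQuantTable(frame)


def write_quant_csv(table: ProteinQuantTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)
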