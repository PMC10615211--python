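"""Number- and volume-weighted size distributions and scalar granule metrics.

A Coulter counter reports particles per diameter bin.  Two relative
distributions are derived from the same counts:

* number weighting — each bin's share is its particle count;
* volume weighting — each bin's count is scaled by the sphere volume
  (pi/6) d^3 at the bin's representative diameter before normalising.

The representative diameter of a bin is the geometric mean of its edges,
consistent with the log-normal modelling downstream.  Shares are
percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ParticleSizeData, ValidationError

__all__ = [
    "DEFAULT_BIN_EDGES",
    "SizeDistribution",
    "GranuleMetrics",
    "bin_particles",
    "to_distribution",
    "percent_small_granules",
    "granules_per_mg",
    "qc_particle_count",
    "write_distribution_csv",
]

# 256 log-spaced edges spanning a plausible 70-um-aperture measuring range
DEFAULT_BIN_EDGES = np.geomspace(1.4, 42.0, 256)

#: QC floor on particles per sample
MIN_PARTICLES = 100_000


@dataclass(frozen=True)
class SizeDistribution:
    """A relative (percent) size distribution on a diameter grid.

    ``grid`` holds bin midpoints (geometric mean of the edges, µm);
    ``relative_share`` the percent of particles (number weighting) or of
    total particle volume (volume weighting) per bin.
    """

    grid: np.ndarray
    relative_share: np.ndarray
    weighting: str
    bin_widths: np.ndarray
    bin_lower: np.ndarray = field(repr=False, default=None)
    bin_upper: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        share = np.asarray(self.relative_share, dtype=float)
        if self.weighting not in ("number", "volume"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if grid.shape != share.shape or grid.ndim != 1:
            raise ValidationError("grid and shares must be 1-D and equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if np.any(share < 0):
            raise ValidationError("shares must be non-negative")
        if abs(share.sum() - 100.0) > 1e-9:
            raise ValidationError("shares must sum to 100")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "relative_share", share)

    @property
    def log_widths(self) -> np.ndarray:
        """Bin widths in ln-diameter, used for density normalisation."""
        return np.log(self.bin_upper / self.bin_lower)


@dataclass
class GranuleMetrics:
    """Scalar phenotype statistics derived from one sample.

    ``b_volume_percent``, ``mean_diameter_A`` and ``mean_diameter_B`` are
    filled by the mixture-fitting stage; ``percent_small_by_number`` and
    ``granules_per_mg`` come straight from the counts.
    """

    percent_small_by_number: float | None = None
    granules_per_mg: float | None = None
    b_volume_percent: float | None = None
    mean_diameter_A: float | None = None
    mean_diameter_B: float | None = None

    def __post_init__(self) -> None:
        for name in ("percent_small_by_number", "b_volume_percent"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")
        if self.granules_per_mg is not None and self.granules_per_mg < 0:
            raise ValidationError("granules_per_mg must be >= 0")


def bin_particles(
    data: ParticleSizeData,
    edges: np.ndarray,
    out_of_range: str = "error",
) -> ParticleSizeData:
    """Bin raw per-particle diameters on half-open ``[lower, upper)`` bins.

    Total particle number is conserved exactly when every diameter falls
    inside ``[edges[0], edges[-1])``; with ``out_of_range="drop"``
    outside particles are discarded instead of raising.
    """
    if data.is_binned:
        raise ValidationError("data is already binned")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("edges must be a strictly increasing 1-D array")
    d = data.raw_diameters
    idx = np.searchsorted(edges, d, side="right") - 1
    inside = (idx >= 0) & (idx <= edges.size - 2)
    if not np.all(inside):
        if out_of_range == "drop":
            idx = idx[inside]
        else:
            bad = d[~inside][0]
            raise ValidationError(
                f"diameter {bad:g} um outside binning range "
                f"[{edges[0]:g}, {edges[-1]:g})"
            )
    counts = np.bincount(idx, minlength=edges.size - 1)
    return ParticleSizeData(
        bin_lower=edges[:-1], bin_upper=edges[1:], count=counts, meta=dict(data.meta)
    )


def to_distribution(
    data: ParticleSizeData,
    weighting: str = "volume",
    edges: np.ndarray | None = None,
) -> SizeDistribution:
    """Convert particle data into a relative percent-vs-diameter distribution.

    Raw data is first binned (on ``edges`` or the default log grid).
    Volume weighting multiplies each bin's count by the sphere volume
    (pi/6) d^3 at the bin's geometric-mean diameter before normalising
    to 100 %.
    """
    if not data.is_binned:
        data = bin_particles(
            data, DEFAULT_BIN_EDGES if edges is None else edges, out_of_range="drop"
        )
    if data.total_count < 1:
        raise ValidationError("no particles to convert")
    mid = np.sqrt(data.bin_lower * data.bin_upper)
    if weighting == "number":
        mass = data.count.astype(float)
    elif weighting == "volume":
        mass = data.count * (np.pi / 6.0) * mid**3
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    share = 100.0 * mass / mass.sum()
    # tidy the float tail so the sum-to-100 invariant holds exactly enough
    share *= 100.0 / share.sum()
    return SizeDistribution(
        grid=mid,
        relative_share=share,
        weighting=weighting,
        bin_widths=data.bin_upper - data.bin_lower,
        bin_lower=data.bin_lower,
        bin_upper=data.bin_upper,
    )


def percent_small_granules(data: ParticleSizeData, threshold: float = 10.0) -> float:
    """Percent of particles (by number) strictly smaller than ``threshold`` µm.

    On raw data this is a direct count.  On binned data, bins entirely
    below the threshold count in full; a bin straddling it is split
    pro-rata by log-width (exact when the threshold coincides with a bin
    edge).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    total = data.total_count
    if total < 1:
        raise ValidationError("no particles")
    if not data.is_binned:
        return 100.0 * float(np.count_nonzero(data.raw_diameters < threshold)) / total
    below = float(data.count[data.bin_upper <= threshold].sum())
    straddle = (data.bin_lower < threshold) & (data.bin_upper > threshold)
    if np.any(straddle):
        (j,) = np.flatnonzero(straddle)
        frac = np.log(threshold / data.bin_lower[j]) / np.log(
            data.bin_upper[j] / data.bin_lower[j]
        )
        below += float(data.count[j]) * frac
    return 100.0 * below / total


def granules_per_mg(
    count_in_analyzed_volume: int,
    analyzed_volume_ml: float,
    total_volume_ml: float,
    fresh_weight_mg: float,
) -> float:
    """Granule number per mg fresh tissue from a volumetric-mode count.

    The counter analyses ``analyzed_volume_ml`` of a suspension of
    ``total_volume_ml``; the count is scaled up to the whole suspension
    and divided by the fresh weight of the dissected tissue.
    """
    if count_in_analyzed_volume < 0:
        raise ValidationError("count must be >= 0")
    if analyzed_volume_ml <= 0 or total_volume_ml <= 0 or fresh_weight_mg <= 0:
        raise ValidationError("volumes and fresh weight must be positive")
    if analyzed_volume_ml > total_volume_ml:
        raise ValidationError("analyzed volume exceeds total suspension volume")
    return (
        count_in_analyzed_volume * (total_volume_ml / analyzed_volume_ml)
    ) / fresh_weight_mg


def qc_particle_count(data: ParticleSizeData, minimum: int = MIN_PARTICLES) -> str:
    """QC flag on the per-sample particle count: ``"pass"`` or ``"warn"``.

    Samples at or above ``minimum`` particles pass; smaller samples warn
    (a :class:`UserWarning` is emitted) but are never rejected.
    """
    if data.total_count >= minimum:
        return "pass"
    warnings.warn(
        f"only {data.total_count} particles measured (minimum {minimum})",
        UserWarning,
        stacklevel=2,
    )
    return "warn"


def write_distribution_csv(dist: SizeDistribution, path) -> None:
    """Export ``diameter_um,share_percent`` rows for plotting."""
    lines = ["diameter_um,share_percent"]
    lines += [
        f"{float(d)!r},{float(s)!r}" for d, s in zip(dist.grid, dist.relative_share)
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
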