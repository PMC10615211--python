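"""Seeded generators for granule populations and pulldown quant tables.

The granule generator draws particle diameters from a one- or
two-component log-normal mixture parameterised on the *volume* scale
(median diameter µm, sigma of ln diameter, volume weight), i.e. the
components as they appear on a relative-volume-vs-diameter plot — the
scale on which the mixture is fitted and on which the phenotype of
interest, the B-type granule volume percentage, is defined.  Sampling
individual particles needs the number-scale mixture, which follows
analytically from the size-bias relation: weighting a log-normal
``LN(mu, sigma)`` by particle volume (d^3) shifts it to
``LN(mu + 3 sigma^2, sigma)``.  Hence per component

    mu_number = ln(median) - 3 sigma^2
    n_k  ∝  v_k * exp(-3 mu_number,k - 4.5 sigma_k^2)

so a fit to the volume-weighted distribution of a generated population
recovers the preset medians, sigmas and volume weights directly.

Counts land on a log-spaced bin grid either as an exact multinomial
draw (counting noise) or as a deterministic largest-remainder
allocation of the expected counts.  Every generator is a pure function
of (spec, seed).

Genotype presets encode the *direction* of the reported mutant
phenotypes, not measured figure values: the *phs1*-like preset has a
smaller B-type volume weight and a larger B-type median than wild type
("fewer and larger B-type granules"); the *bgc1*-like preset has no
B component; the early-development preset is unimodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import DEFAULT_BIN_EDGES
from .io import ParticleSizeData, ProteinQuantTable, ValidationError

__all__ = [
    "GENOTYPE_PRESETS",
    "DEVELOPMENT_PRESETS",
    "SyntheticSpec",
    "SyntheticQuantSpec",
    "simulate_granules",
    "sample_raw_diameters",
    "simulate_development_series",
    "simulate_quant_table",
]

# (median diameter um, sigma of ln d, volume weight); B component first
GENOTYPE_PRESETS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "WT": ((5.0, 0.30, 0.30), (21.0, 0.22, 0.70)),
    "phs1_like": ((7.5, 0.30, 0.12), (21.0, 0.22, 0.88)),
    "bgc1_like": ((21.0, 0.22, 1.0),),
    "unimodal_early": ((10.0, 0.35, 1.0),),
}

# developmental series over days post anthesis: unimodal (A only) at 8 and
# 14 dpa, bimodal from 18 dpa once B-type granules have initiated; mutant
# presets show a smaller, larger-median B component at the late timepoints
DEVELOPMENT_PRESETS: dict[str, dict[int, tuple[tuple[float, float, float], ...]]] = {
    "WT": {
        8: ((7.0, 0.35, 1.0),),
        14: ((12.0, 0.30, 1.0),),
        18: ((4.5, 0.30, 0.15), (18.0, 0.24, 0.85)),
        22: ((5.0, 0.30, 0.30), (21.0, 0.22, 0.70)),
    },
    "phs1_like": {
        8: ((7.0, 0.35, 1.0),),
        14: ((12.0, 0.30, 1.0),),
        18: ((6.5, 0.30, 0.05), (18.0, 0.24, 0.95)),
        22: ((7.5, 0.30, 0.12), (21.0, 0.22, 0.88)),
    },
    "bgc1_like": {
        8: ((7.0, 0.35, 1.0),),
        14: ((12.0, 0.30, 1.0),),
        18: ((18.0, 0.24, 1.0),),
        22: ((21.0, 0.22, 1.0),),
    },
}

DEVELOPMENT_TIMEPOINTS = (8, 14, 18, 22)


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of a seeded granule-population draw."""

    seed: int
    components: tuple[tuple[float, float, float], ...] = GENOTYPE_PRESETS["WT"]
    n_particles: int = 100_000
    noise: str = "multinomial"
    genotype_preset: str | None = None
    bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_EDGES.copy())

    def __post_init__(self) -> None:
        comps = tuple(tuple(float(v) for v in c) for c in self.components)
        if not comps:
            raise ValidationError("at least one component required")
        medians = [c[0] for c in comps]
        sigmas = [c[1] for c in comps]
        weights = [c[2] for c in comps]
        if any(m <= 0 for m in medians) or any(s <= 0 for s in sigmas):
            raise ValidationError("medians and sigmas must be positive")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("volume weights must be non-negative and sum to 1")
        if self.noise not in ("none", "multinomial"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))

    @classmethod
    def from_preset(
        cls,
        name: str,
        seed: int,
        n_particles: int = 100_000,
        noise: str = "multinomial",
    ) -> "SyntheticSpec":
        if name not in GENOTYPE_PRESETS:
            raise ValidationError(
                f"unknown preset {name!r}; choose from {sorted(GENOTYPE_PRESETS)}"
            )
        return cls(
            seed=seed,
            components=GENOTYPE_PRESETS[name],
            n_particles=n_particles,
            noise=noise,
            genotype_preset=name,
        )

    def number_scale_mus(self) -> np.ndarray:
        """Number-scale ln-medians: ln(median) - 3 sigma^2 per component."""
        mus_vol = np.log([c[0] for c in self.components])
        sigmas = np.array([c[1] for c in self.components])
        return mus_vol - 3.0 * sigmas**2

    def number_weights(self) -> np.ndarray:
        """Per-particle mixing weights implied by the volume weights."""
        mus_num = self.number_scale_mus()
        sigmas = np.array([c[1] for c in self.components])
        vols = np.array([c[2] for c in self.components])
        raw = vols * np.exp(-3.0 * mus_num - 4.5 * sigmas**2)
        return raw / raw.sum()

    def truth(self) -> dict:
        """Ground-truth record returned alongside generated data."""
        nw = self.number_weights()
        mus_num = self.number_scale_mus()
        return {
            "seed": int(self.seed),
            "n_particles": int(self.n_particles),
            "noise": self.noise,
            "genotype_preset": self.genotype_preset,
            "components": [
                {
                    "median_um": c[0],
                    "mu": math.log(c[0]),
                    "mu_number": float(mus_num[k]),
                    "sigma": c[1],
                    "volume_weight": c[2],
                    "number_weight": float(nw[k]),
                }
                for k, c in enumerate(self.components)
            ],
        }


def _bin_probabilities(spec: SyntheticSpec) -> np.ndarray:
    """Mixture bin probabilities on the grid, renormalised over its range."""
    log_edges = np.log(spec.bin_edges)
    nw = spec.number_weights()
    mus_num = spec.number_scale_mus()
    probs = np.zeros(spec.bin_edges.size - 1)
    for (_, sigma, _), mu, w in zip(spec.components, mus_num, nw):
        cdf = stats.norm.cdf(log_edges, loc=mu, scale=sigma)
        probs += w * np.diff(cdf)
    total = probs.sum()
    if total <= 0:
        raise ValidationError("mixture places no mass on the bin grid")
    return probs / total


def simulate_granules(spec: SyntheticSpec) -> tuple[ParticleSizeData, dict]:
    """Draw a binned granule population; returns (data, ground truth).

    ``noise="multinomial"`` draws bin counts as a multinomial sample of
    ``n_particles`` (the counting noise of sampling individual
    particles); ``noise="none"`` allocates the expected counts
    deterministically by largest remainder, conserving the total.
    Bit-reproducible given the spec (which includes the seed).
    """
    probs = _bin_probabilities(spec)
    if spec.noise == "multinomial":
        rng = np.random.default_rng(spec.seed)
        counts = rng.multinomial(spec.n_particles, probs)
    else:
        expected = probs * spec.n_particles
        counts = np.floor(expected).astype(np.int64)
        short = spec.n_particles - int(counts.sum())
        if short > 0:
            order = np.argsort(-(expected - counts), kind="stable")
            counts[order[:short]] += 1
    meta = {"sample_id": spec.genotype_preset or "synthetic"}
    data = ParticleSizeData(
        bin_lower=spec.bin_edges[:-1],
        bin_upper=spec.bin_edges[1:],
        count=counts,
        meta=meta,
    )
    return data, spec.truth()


def sample_raw_diameters(
    spec: SyntheticSpec, return_labels: bool = False
) -> tuple[ParticleSizeData, dict] | tuple[ParticleSizeData, dict, np.ndarray]:
    """Draw raw per-particle diameters from the (grid-truncated) mixture.

    Diameters are resampled until they fall inside the bin-grid range,
    so raw and binned draws of the same spec describe the same
    truncated population; the truncated tail mass is < 1e-3 for all
    presets.  With ``return_labels`` the per-particle component index is
    returned as a third element.
    """
    rng = np.random.default_rng(spec.seed)
    nw = spec.number_weights()
    mus = spec.number_scale_mus()
    sigmas = np.array([c[1] for c in spec.components])
    lo, hi = spec.bin_edges[0], spec.bin_edges[-1]
    out = np.empty(spec.n_particles)
    out_labels = np.empty(spec.n_particles, dtype=np.int64)
    filled = 0
    while filled < spec.n_particles:
        need = spec.n_particles - filled
        labels = rng.choice(len(nw), size=need, p=nw)
        d = np.exp(rng.normal(mus[labels], sigmas[labels]))
        inside = (d >= lo) & (d < hi)
        keep = d[inside]
        out[filled : filled + keep.size] = keep
        out_labels[filled : filled + keep.size] = labels[inside]
        filled += keep.size
    meta = {"sample_id": spec.genotype_preset or "synthetic"}
    data = ParticleSizeData(raw_diameters=out, meta=meta)
    if return_labels:
        return data, spec.truth(), out_labels
    return data, spec.truth()


def simulate_development_series(
    genotype: str = "WT",
    seed: int = 0,
    n_particles: int = 100_000,
    timepoints: Sequence[int] = DEVELOPMENT_TIMEPOINTS,
    noise: str = "multinomial",
) -> dict[int, tuple[ParticleSizeData, dict]]:
    """Granule populations across grain development (days post anthesis).

    Returns ``{dpa: (data, truth)}`` for the requested genotype; each
    timepoint uses a sub-seed derived from ``seed`` so the series is
    reproducible as a whole.
    """
    if genotype not in DEVELOPMENT_PRESETS:
        raise ValidationError(
            f"unknown genotype {genotype!r}; choose from {sorted(DEVELOPMENT_PRESETS)}"
        )
    series = {}
    for dpa in timepoints:
        if dpa not in DEVELOPMENT_PRESETS[genotype]:
            raise ValidationError(f"no preset for {genotype!r} at {dpa} dpa")
        spec = SyntheticSpec(
            seed=(seed * 1009 + dpa) % (2**31),
            components=DEVELOPMENT_PRESETS[genotype][dpa],
            n_particles=n_particles,
            noise=noise,
            genotype_preset=f"{genotype}_{dpa}dpa",
        )
        series[dpa] = simulate_granules(spec)
    return series


@dataclass(frozen=True)
class SyntheticQuantSpec:
    """Configuration of a seeded replicate proteomics table.

    Background proteins have unit true pulldown/control ratio; a spiked
    subset is shifted by ``log_fold_effect`` in the pulldown.  Replicate
    scatter is log-normal with coefficient of variation
    ``replicate_cv``.
    """

    seed: int
    n_background: int = 200
    n_enriched: int = 20
    log_fold_effect: float = math.log(4.0)
    replicate_cv: float = 0.2
    n_replicates: int = 3
    ratio_cap: float = 100.0

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_enriched < 0:
            raise ValidationError("protein counts must be >= 0")
        if self.n_background + self.n_enriched == 0:
            raise ValidationError("table must contain at least one protein")
        if self.replicate_cv <= 0:
            raise ValidationError("replicate CV must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per condition")


def simulate_quant_table(
    spec: SyntheticQuantSpec,
) -> tuple[ProteinQuantTable, np.ndarray]:
    """Replicate abundance table with a spiked enriched subset.

    Returns the table and a boolean truth vector marking the enriched
    proteins (accessions are also prefixed ``EN``/``BG``).
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_background + spec.n_enriched
    enriched = np.zeros(n_total, dtype=bool)
    enriched[: spec.n_enriched] = True
    # baseline log-abundance per protein; replicate scatter from the CV
    base = rng.normal(math.log(1e6), 1.0, size=n_total)
    sigma = math.sqrt(math.log1p(spec.replicate_cv**2))
    shape = (n_total, spec.n_replicates)
    log_ctrl = base[:, None] + rng.normal(0.0, sigma, size=shape)
    log_pd = (
        base[:, None]
        + np.where(enriched, spec.log_fold_effect, 0.0)[:, None]
        + rng.normal(0.0, sigma, size=shape)
    )
    accession = [
        f"EN{i + 1:04d}" if enriched[i] else f"BG{i + 1:04d}" for i in range(n_total)
    ]
    data = {"accession": accession}
    for r in range(spec.n_replicates):
        data[f"pd_{r + 1}"] = np.exp(log_pd[:, r])
    for r in range(spec.n_replicates):
        data[f"ctrl_{r + 1}"] = np.exp(log_ctrl[:, r])
    return ProteinQuantTable(pd.DataFrame(data)), enriched


# re-exported convenience: a spec with a different seed
def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
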