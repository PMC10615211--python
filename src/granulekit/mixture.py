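"""Log-normal mixture deconvolution of volume-weighted size distributions.

Wheat endosperm starch holds two granule populations: large discoid
A-type granules initiated early in grain development and small spherical
B-type granules initiated around 15–20 days post anthesis.  On a
volume-weighted diameter distribution the two appear as a bimodal curve
that is well described by a two-component log-normal mixture; the mixing
weight of the small-diameter component estimates the B-type granule
volume percentage, and each component's ``exp(mu + sigma^2/2)`` gives a
(volume-weighted) mean granule diameter.

The fit target is the volume-share *density per unit ln(diameter)* —
shares divided by log bin width — which makes the objective independent
of the binning grid.  Fitting is bounded multi-start local least
squares: starts are drawn from a seeded grid around 5 µm and 20 µm
medians with sigma in {0.15, 0.3, 0.5} and B-weight in {0.1, 0.3, 0.5};
the start with the lowest sum of squared residuals wins, ties broken by
lower start index.  Given a seed the whole procedure is deterministic.

Number-weighted distributions are rejected: the A-type peak is far too
small on a number basis for a reliable fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .distributions import GranuleMetrics, SizeDistribution
from .io import GranulekitError, ValidationError

__all__ = [
    "FitError",
    "LogNormalComponent",
    "MixtureFit",
    "fit_mixture",
    "derive_granule_metrics",
    "choose_model",
    "MINOR_WEIGHT_FLOOR",
]


class FitError(GranulekitError, RuntimeError):
    """No optimisation start converged."""


#: automatic unimodal fallback: minor component weights below this are
#: treated as spurious
MINOR_WEIGHT_FLOOR = 0.02

#: automatic unimodal fallback: minimum Ashman's D between the two fitted
#: components.  D = |mu_A - mu_B| / sqrt((sigma_A^2 + sigma_B^2)/2); below 2
#: two Gaussians cannot produce a bimodal curve, so the second component is
#: just splitting a single peak
MIN_COMPONENT_SEPARATION = 2.0

#: automatic unimodal fallback: a genuine second mode reduces the residual
#: sum of squares several-fold, while fitting counting noise barely helps;
#: the two-component fit must reach sse2 <= MAX_SSE_RATIO * sse1 to count
MAX_SSE_RATIO = 0.7

# optimiser bounds and tolerances (fixed for reproducibility)
_MU_BOUNDS = (math.log(0.5), math.log(60.0))
_SIGMA_BOUNDS = (0.02, 1.5)
_W_BOUNDS = (1e-6, 1.0 - 1e-6)
_SSE_TOL = 1e-10
_MAX_ITER = 500

_SIGMA_STARTS = (0.15, 0.3, 0.5)
_W_STARTS = (0.1, 0.3, 0.5)
_MEDIAN_B_START = 5.0
_MEDIAN_A_START = 20.0


@dataclass(frozen=True)
class LogNormalComponent:
    """One log-normal component: ``ln d ~ N(mu, sigma^2)``, mixing ``weight``."""

    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError("weight must lie in [0, 1]")

    @property
    def median(self) -> float:
        """Median diameter exp(mu), µm."""
        return math.exp(self.mu)

    @property
    def mean_diameter(self) -> float:
        """Mean diameter exp(mu + sigma^2/2) of the fitted component, µm."""
        return math.exp(self.mu + self.sigma**2 / 2.0)


@dataclass(frozen=True)
class MixtureFit:
    """Result of a mixture fit; components ordered B (smaller median) first."""

    components: tuple[LogNormalComponent, ...]
    sse: float
    converged: bool
    n_starts_used: int
    fitted_curve: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.components) not in (1, 2):
            raise ValidationError("a fit has one or two components")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("component weights must sum to 1")
        if len(self.components) == 2:
            if not self.components[0].median < self.components[1].median:
                raise ValidationError("B component must have the smaller median")
        if self.sse < 0:
            raise ValidationError("sse must be >= 0")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def component_A(self) -> LogNormalComponent:
        """The large-granule component (the sole component when unimodal)."""
        return self.components[-1]

    @property
    def component_B(self) -> LogNormalComponent | None:
        """The small-granule component, or None for a unimodal fit."""
        return self.components[0] if self.n_components == 2 else None

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "components": [
                {
                    "label": lab,
                    "mu": c.mu,
                    "sigma": c.sigma,
                    "weight": c.weight,
                    "median_um": c.median,
                    "mean_diameter_um": c.mean_diameter,
                }
                for lab, c in zip(
                    ("B", "A") if self.n_components == 2 else ("A",), self.components
                )
            ],
            "sse": self.sse,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def _density_target(dist: SizeDistribution) -> tuple[np.ndarray, np.ndarray]:
    """(ln-diameter grid, observed density per unit ln d integrating to 1)."""
    if dist.bin_lower is None or dist.bin_upper is None:
        raise ValidationError("distribution lacks bin edges needed for fitting")
    x = np.log(dist.grid)
    y = dist.relative_share / 100.0 / dist.log_widths
    return x, y


def _model(params: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        mu, sigma = params
        return _normal_pdf(x, mu, sigma)
    mu_b, sigma_b, w, mu_a, sigma_a = params
    return w * _normal_pdf(x, mu_b, sigma_b) + (1.0 - w) * _normal_pdf(
        x, mu_a, sigma_a
    )


def _starts(k: int, n_starts: int, seed: int, x: np.ndarray, y: np.ndarray):
    """Deterministic list of optimisation starting points."""
    rng = np.random.default_rng(seed)
    starts = []
    if k == 2:
        grid = [
            (sb, sa, w)
            for sb in _SIGMA_STARTS
            for sa in _SIGMA_STARTS
            for w in _W_STARTS
        ]
        for i in range(n_starts):
            sb, sa, w = grid[i % len(grid)]
            jb, ja = rng.uniform(-0.1, 0.1, size=2)
            starts.append(
                np.array(
                    [
                        math.log(_MEDIAN_B_START) + jb,
                        sb,
                        w,
                        math.log(_MEDIAN_A_START) + ja,
                        sa,
                    ]
                )
            )
    else:
        # moment-based centre plus the sigma grid
        mean_x = float(np.sum(x * y * np.gradient(x)) / np.sum(y * np.gradient(x)))
        for i in range(n_starts):
            s = _SIGMA_STARTS[i % len(_SIGMA_STARTS)]
            j = rng.uniform(-0.1, 0.1)
            starts.append(np.array([mean_x + j, s]))
    return starts


def fit_mixture(
    dist: SizeDistribution,
    n_components: int = 2,
    n_starts: int = 16,
    seed: int = 0,
) -> MixtureFit:
    """Fit a one- or two-component log-normal mixture to a volume distribution.

    Parameters
    ----------
    dist
        Volume-weighted :class:`SizeDistribution` with at least 8
        non-empty bins.
    n_components
        1 (unimodal, e.g. early development or *bgc1*-like samples) or 2.
    n_starts
        Number of multi-start local optimisations.
    seed
        Seeds the start-point jitter; the fit is deterministic given it.
    """
    if dist.weighting != "volume":
        raise ValidationError(
            "fit_mixture requires a volume-weighted distribution; the A-type "
            "peak is too small on a number basis for a reliable fit"
        )
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    if int(np.count_nonzero(dist.relative_share > 0)) < 8:
        raise ValidationError("need at least 8 bins with nonzero share")

    x, y = _density_target(dist)
    k = n_components
    if k == 1:
        lower = [_MU_BOUNDS[0], _SIGMA_BOUNDS[0]]
        upper = [_MU_BOUNDS[1], _SIGMA_BOUNDS[1]]
    else:
        lower = [_MU_BOUNDS[0], _SIGMA_BOUNDS[0], _W_BOUNDS[0]] + [
            _MU_BOUNDS[0],
            _SIGMA_BOUNDS[0],
        ]
        upper = [_MU_BOUNDS[1], _SIGMA_BOUNDS[1], _W_BOUNDS[1]] + [
            _MU_BOUNDS[1],
            _SIGMA_BOUNDS[1],
        ]

    best = None
    diagnostics = []
    for i, p0 in enumerate(_starts(k, n_starts, seed, x, y)):
        res = least_squares(
            lambda p: _model(p, x, k) - y,
            p0,
            bounds=(lower, upper),
            method="trf",
            ftol=_SSE_TOL,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=_MAX_ITER * (len(p0) + 1),
        )
        sse = float(np.sum(res.fun**2))
        ok = res.status > 0
        diagnostics.append((i, sse, res.status))
        if ok and (best is None or sse < best[0]):
            best = (sse, i, res)
    if best is None:
        raise FitError(f"no start converged; diagnostics: {diagnostics}")

    sse, _, res = best
    p = res.x
    if k == 1:
        comps = (LogNormalComponent(mu=float(p[0]), sigma=float(p[1]), weight=1.0),)
    else:
        mu_b, sigma_b, w, mu_a, sigma_a = (float(v) for v in p)
        if mu_b > mu_a:  # relabel so B is the smaller-median component
            mu_b, sigma_b, mu_a, sigma_a, w = mu_a, sigma_a, mu_b, sigma_b, 1.0 - w
        comps = (
            LogNormalComponent(mu=mu_b, sigma=sigma_b, weight=w),
            LogNormalComponent(mu=mu_a, sigma=sigma_a, weight=1.0 - w),
        )
    fitted_density = _model(p, x, k)
    fitted_curve = fitted_density * dist.log_widths * 100.0
    return MixtureFit(
        components=comps,
        sse=sse,
        converged=True,
        n_starts_used=n_starts,
        fitted_curve=fitted_curve,
        seed=seed,
    )


def derive_granule_metrics(fit: MixtureFit) -> GranuleMetrics:
    """B-type volume percent and mean component diameters from a fit.

    A unimodal fit yields ``b_volume_percent = 0`` and no B diameter.
    """
    if not fit.converged:
        raise FitError("cannot derive metrics from an unconverged fit")
    if fit.n_components == 1:
        return GranuleMetrics(
            b_volume_percent=0.0,
            mean_diameter_A=fit.component_A.mean_diameter,
            mean_diameter_B=None,
        )
    return GranuleMetrics(
        b_volume_percent=100.0 * fit.component_B.weight,
        mean_diameter_A=fit.component_A.mean_diameter,
        mean_diameter_B=fit.component_B.mean_diameter,
    )


def ashman_d(fit: MixtureFit) -> float:
    """Ashman's bimodality separation D between the two fitted components."""
    if fit.n_components != 2:
        raise ValidationError("Ashman's D needs a two-component fit")
    b, a = fit.components
    return abs(a.mu - b.mu) / math.sqrt((a.sigma**2 + b.sigma**2) / 2.0)


def choose_model(
    dist: SizeDistribution,
    force_unimodal: bool = False,
    n_starts: int = 16,
    seed: int = 0,
    minor_weight_floor: float = MINOR_WEIGHT_FLOOR,
    min_separation: float = MIN_COMPONENT_SEPARATION,
    max_sse_ratio: float = MAX_SSE_RATIO,
) -> int:
    """Model order (1 or 2) for a sample.

    ``force_unimodal`` pins the order to 1 (used for *bgc1*-like
    genotypes that lack a B-type peak).  Otherwise a two-component fit
    is attempted and demoted to one component when it is spurious by
    any of three signs: the minor weight falls below
    ``minor_weight_floor``; the components overlap so heavily (Ashman's
    D below ``min_separation``) that they split a single peak rather
    than resolve two modes; or the second component barely improves the
    residuals over a one-component fit (sse ratio above
    ``max_sse_ratio``, the signature of fitting counting noise).
    """
    if force_unimodal:
        return 1
    fit2 = fit_mixture(dist, n_components=2, n_starts=n_starts, seed=seed)
    minor = min(c.weight for c in fit2.components)
    if minor < minor_weight_floor or ashman_d(fit2) < min_separation:
        return 1
    fit1 = fit_mixture(dist, n_components=1, n_starts=n_starts, seed=seed)
    if fit1.sse > 0 and fit2.sse / fit1.sse > max_sse_ratio:
        return 1
    return 2
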