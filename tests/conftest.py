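"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from granulekit import SizeDistribution


def volume_dist_from_components(components, n_bins=120, lo=1.4, hi=42.0):
    """Noise-free volume-share distribution from ln-scale normal components.

    ``components`` are (mu, sigma, weight) triples of the volume-weighted
    density per unit ln(diameter); shares are exact CDF differences on a
    log-spaced grid.  Built directly from scipy here so fits can be
    checked against known parameters without going through the package's
    own generator.
    """
    edges = np.geomspace(lo, hi, n_bins + 1)
    log_edges = np.log(edges)
    mass = np.zeros(n_bins)
    for mu, sigma, w in components:
        cdf = stats.norm.cdf(log_edges, loc=mu, scale=sigma)
        mass += w * np.diff(cdf)
    share = 100.0 * mass / mass.sum()
    return SizeDistribution(
        grid=np.sqrt(edges[:-1] * edges[1:]),
        relative_share=share,
        weighting="volume",
        bin_widths=np.diff(edges),
        bin_lower=edges[:-1],
        bin_upper=edges[1:],
    )


def bh_step_up(p):
    """Brute-force Benjamini–Hochberg step-up from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


@pytest.fixture
def wt_volume_dist():
    """Noise-free wild-type-like bimodal volume distribution."""
    return volume_dist_from_components(
        [(np.log(5.0), 0.25, 0.30), (np.log(20.0), 0.20, 0.70)]
    )
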