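"""Pulldown-vs-control enrichment statistics and the significance filter.

For each protein, three pulldown replicates are compared with three
no-bait control replicates: the abundance ratio is the mean pulldown
abundance over the mean control abundance (capped at 100, mirroring the
saturated values seen in instrument exports), significance comes from a
Welch (unequal-variance) two-sample t-test on log-transformed
abundances, and p-values may be adjusted with Benjamini–Hochberg.  The
filter retains proteins with at least 2-fold enrichment at P < 0.05
(raw p by default).

The Welch t-test is a documented replacement for the proprietary
"background-based" test of the original acquisition software, not a
reimplementation of it; missing abundance values are rejected rather
than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantTable, ValidationError

__all__ = [
    "RATIO_CAP",
    "P_FLOOR",
    "EnrichmentResult",
    "compute_ratios",
    "test_enrichment",
    "bh_adjust",
    "filter_enriched",
    "analyze_pulldown",
]

# saturation conventions matching typical instrument-software exports
RATIO_CAP = 100.0
P_FLOOR = 1e-17


@dataclass(frozen=True)
class EnrichmentResult:
    """Full annotated table plus the subset passing the filter."""

    table: ProteinQuantTable
    retained: pd.DataFrame
    fold: float
    alpha: float
    use_adjusted: bool

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def compute_ratios(table: ProteinQuantTable, cap: float = RATIO_CAP) -> ProteinQuantTable:
    """Add a ``ratio`` column: mean(pulldown)/mean(control), capped."""
    if table.n_replicates == 0:
        raise ValidationError("replicate abundances required to compute ratios")
    ratio = table.pulldown_matrix().mean(axis=1) / table.control_matrix().mean(axis=1)
    frame = table.frame.copy()
    frame["ratio"] = np.minimum(ratio, cap)
    return ProteinQuantTable(frame)


def test_enrichment(table: ProteinQuantTable, p_floor: float = P_FLOOR) -> ProteinQuantTable:
    """Add a ``p_value`` column from a Welch t-test on ln abundances.

    Degenerate rows where both groups have zero variance yield p = 1
    when the means agree (no evidence of enrichment) and the p floor
    when they differ (perfect separation).
    """
    if table.n_replicates == 0:
        raise ValidationError("replicate abundances required for the t-test")
    log_pd = np.log(table.pulldown_matrix())
    log_ctrl = np.log(table.control_matrix())
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(log_pd, log_ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        same = np.isclose(log_pd.mean(axis=1), log_ctrl.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = p_floor
    p = np.clip(p, p_floor, 1.0)
    frame = table.frame.copy()
    frame["p_value"] = p
    return ProteinQuantTable(frame)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_enriched(
    table: ProteinQuantTable,
    fold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> EnrichmentResult:
    """Retain proteins with ratio >= ``fold`` and p < ``alpha``.

    Filters on the raw p-value by default (matching the stated
    criterion); ``use_adjusted`` switches to BH-adjusted p-values,
    computing them if absent.
    """
    frame = table.frame.copy()
    if "ratio" not in frame.columns or "p_value" not in frame.columns:
        raise ValidationError("table needs ratio and p_value columns; run "
                              "compute_ratios/test_enrichment first")
    if use_adjusted and "p_adjusted" not in frame.columns:
        frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy(float))
    p_col = "p_adjusted" if use_adjusted else "p_value"
    mask = (frame["ratio"].to_numpy(float) >= fold) & (
        frame[p_col].to_numpy(float) < alpha
    )
    annotated = ProteinQuantTable(frame)
    return EnrichmentResult(
        table=annotated,
        retained=frame.loc[mask].reset_index(drop=True),
        fold=fold,
        alpha=alpha,
        use_adjusted=use_adjusted,
    )


def analyze_pulldown(
    table: ProteinQuantTable,
    fold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    cap: float = RATIO_CAP,
) -> EnrichmentResult:
    """Full pipeline: ratios, Welch t-test, BH adjustment, filter."""
    table = compute_ratios(table, cap=cap)
    table = test_enrichment(table)
    frame = table.frame.copy()
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy(float))
    return filter_enriched(
        ProteinQuantTable(frame), fold=fold, alpha=alpha, use_adjusted=use_adjusted
    )
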