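"""Covariate correlations and genome-window clustering summaries.

Sequencing depth and library insert size both influence how many SVs a
pipeline can detect (longer inserts span breakpoints more often), so
per-call-set SV totals are correlated against those summaries.  Singleton
calls are additionally binned into fixed genome windows to ask whether the
variable calls pile up anywhere; the window test here is a Poisson maximum
test with Bonferroni correction, this package's own choice of statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SVRecord

#: Covariate columns expected in a call-set covariate table.
COVARIATE_COLUMNS = ("mean_coverage", "sd_coverage", "mean_insert", "sd_insert")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p value.

    The p value comes from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom.  Vectors must have equal length >= 3 and
    non-zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class WindowCounts:
    """Singleton counts per fixed-size genome window (zeros included)."""

    window_size: int
    genome: dict[str, int]
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return sum(-(-length // self.window_size) for length in self.genome.values())

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def values(self) -> np.ndarray:
        """All window counts, zeros included, in genome order."""
        out = []
        for contig in self.genome:
            n = -(-self.genome[contig] // self.window_size)
            for w in range(n):
                out.append(self.counts.get((contig, w), 0))
        return np.asarray(out, dtype=int)


def window_singleton_counts(singletons, window_size: int,
                            genome: dict[str, int]) -> WindowCounts:
    """Assign each singleton to the window containing its start position.

    Window index is ``floor((start - 1) / window_size)`` (VCF 1-based
    starts; position 100,000 falls in window 0 of a 100 kb grid, 100,001 in
    window 1).
    """
    wc = WindowCounts(window_size=window_size, genome=dict(genome))
    for item in singletons:
        r: SVRecord = item.representative if hasattr(item, "representative") else item
        if r.contig not in genome:
            raise ValueError(f"record {r.id!r} on contig {r.contig!r} absent from genome")
        if r.start > genome[r.contig]:
            raise ValueError(f"record {r.id!r} start {r.start} beyond contig length")
        idx = (r.start - 1) // window_size
        wc.counts[(r.contig, idx)] = wc.counts.get((r.contig, idx), 0) + 1
    return wc


@dataclass
class ClusteringSummary:
    """Poisson maximum test of window counts against a uniform background."""

    max_count: int
    rate: float
    p_value: float
    n_windows: int
    alpha: float
    significant: bool


def clustering_summary(w: WindowCounts, alpha: float = 0.05) -> ClusteringSummary:
    """Test whether the fullest window is overloaded relative to uniform.

    Under a uniform placement of N singletons over W windows each count is
    approximately Poisson(N/W); the upper tail probability of the observed
    maximum is Bonferroni-corrected across the W windows.  This is a
    deliberately conservative screen for hotspots, not a spatial model.
    """
    if w.n_windows == 0:
        raise ValueError("no windows: empty genome or zero window size")
    values = w.values()
    lam = w.total / w.n_windows
    max_count = int(values.max()) if len(values) else 0
    p = float(stats.poisson.sf(max_count - 1, lam))  # P(X >= max)
    significant = bool(p * w.n_windows < alpha)
    return ClusteringSummary(max_count=max_count, rate=lam, p_value=p,
                             n_windows=w.n_windows, alpha=alpha,
                             significant=significant)


def covariate_correlations(table: pd.DataFrame,
                           response: str = "total_svs",
                           covariates=COVARIATE_COLUMNS) -> pd.DataFrame:
    """Pearson r and p of the SV total against each covariate column.

    Zero-variance columns are reported with an error message rather than
    aborting the remaining columns.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 call sets")
    rows = []
    y = table[response].to_numpy(dtype=float)
    for col in covariates:
        if col not in table.columns:
            continue
        try:
            r, p = pearson(table[col].to_numpy(dtype=float), y)
            rows.append({"covariate": col, "r": r, "p_value": p, "error": ""})
        except ValueError as exc:
            rows.append({"covariate": col, "r": np.nan, "p_value": np.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows)
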