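"""Frequency distributions over pooled-range bins, categories and ECDFs.

Confinement ratios and diffusion coefficients are visualized as "% of
particle population" histograms.  The binning grid is shared across all
experimental conditions: the pooled values of every condition set the range,
which is divided into equal-width bins (10 for confinement, 12 for diffusion
by convention here).  Bins are left-inclusive / right-exclusive except the
last, which is right-inclusive so the pooled maximum is conserved.

Bins may carry qualitative category labels (slow/intermediate/fast diffusion,
light/medium/high confinement).  Labels are a visualization aid only — no
statistic in this package reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gliotrack")

__all__ = [
    "BinningScheme",
    "FrequencyDistribution",
    "ECDF",
    "pooled_range_bins",
    "frequency_distribution",
    "assign_categories",
    "ecdf",
]


@dataclass(frozen=True)
class BinningScheme:
    edges: np.ndarray  # strictly increasing, len = n_bins + 1
    categories: dict[int, str] = field(default_factory=dict)  # bin index -> label

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing (>= 2 edges)")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 marks out-of-range.  Last bin is closed."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="right") - 1
        idx[v == self.edges[-1]] = self.n_bins - 1
        idx[(v < self.edges[0]) | (v > self.edges[-1])] = -1
        return idx


@dataclass(frozen=True)
class FrequencyDistribution:
    scheme: BinningScheme
    percent: np.ndarray  # % of n_total per bin (all bins)
    n_total: int
    n_out_of_range: int = 0
    drop_first_bin: bool = False

    @property
    def graphed_percent(self) -> np.ndarray:
        """Percentages as plotted: the first bin may be suppressed for
        readability while still counting toward n_total."""
        if self.drop_first_bin:
            return self.percent[1:]
        return self.percent

    @property
    def graphed_edges(self) -> np.ndarray:
        if self.drop_first_bin:
            return self.scheme.edges[1:]
        return self.scheme.edges


def pooled_range_bins(values_all_conditions, n_bins: int) -> BinningScheme:
    """Equal-width bins spanning the pooled [min, max] of all conditions."""
    v = np.asarray(values_all_conditions, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2 or v.min() == v.max():
        raise ValueError("pooled_range_bins needs >= 2 distinct values")
    return BinningScheme(np.linspace(v.min(), v.max(), n_bins + 1))


def frequency_distribution(
    values, scheme: BinningScheme, drop_first_bin: bool = False
) -> FrequencyDistribution:
    """Percent of the population per bin.

    ``drop_first_bin`` implements the plotting convention of suppressing a
    dominant first bin from the graph: the bin is excluded from the graphed
    output only, while ``n_total`` (the denominator of every percentage)
    still counts it, and statistics elsewhere always use the full population.
    """
    v = np.asarray(values, dtype=float)
    n_total = len(v)
    if n_total == 0:
        raise ValueError("frequency_distribution needs >= 1 value")
    idx = scheme.bin_of(v)
    n_out = int((idx == -1).sum())
    if n_out:
        logger.warning("frequency_distribution: %d value(s) out of range", n_out)
    counts = np.bincount(idx[idx >= 0], minlength=scheme.n_bins)
    return FrequencyDistribution(
        scheme=scheme,
        percent=100.0 * counts / n_total,
        n_total=n_total,
        n_out_of_range=n_out,
        drop_first_bin=drop_first_bin,
    )


def assign_categories(
    scheme: BinningScheme,
    boundaries: tuple[int, int] | None = None,
    labels: tuple[str, str, str] = ("low", "mid", "high"),
) -> BinningScheme:
    """Attach three contiguous category labels to the bins.

    ``boundaries = (b1, b2)`` assigns bins 1..b1 the first label, b1+1..b2
    the second and b2+1..n_bins the third (1-based, matching histogram
    reading order).  Default: equal thirds of the bin range.  Labels are
    cosmetic; the stats layer never reads them.
    """
    n = scheme.n_bins
    if boundaries is None:
        boundaries = (round(n / 3), round(2 * n / 3))
    b1, b2 = boundaries
    if not (1 <= b1 < b2 < n):
        raise ValueError(
            f"category boundaries {boundaries} do not split {n} bins into 3 contiguous groups"
        )
    cats = {}
    for i in range(n):
        cats[i] = labels[0] if i < b1 else labels[1] if i < b2 else labels[2]
    return BinningScheme(scheme.edges.copy(), cats)


class ECDF:
    """Right-continuous empirical CDF, evaluable at arbitrary points."""

    def __init__(self, values) -> None:
        v = np.asarray(values, dtype=float)
        if len(v) == 0:
            raise ValueError("ecdf needs >= 1 value")
        self.values = np.sort(v)
        self.n = len(v)

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def ecdf(values) -> ECDF:
    return ECDF(values)
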