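"""Tree/field crop index and proxy cross-correlation.

The crop index summarizes the compositional balance of an assemblage between
perennial tree crops (avocado, hog plum, sapote ...) and annual field crops
(maize, beans, squash ...):

    index = (field - tree) / (field + tree)

scaled so that -1 means 100% tree crops and +1 means 100% field crops.
Specimens in other categories are excluded from the denominator.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from shelterchron.event_density import TimeSeries


def crop_index(tree: int, field: int) -> float:
    """Tree/field compositional index in [-1, +1].

    Returns NaN when the assemblage holds neither tree nor field specimens
    (undefined, reported as missing rather than 0). Antisymmetric: swapping
    the counts negates the index.
    """
    if tree < 0 or field < 0:
        raise ValueError("counts must be non-negative")
    total = tree + field
    if total == 0:
        return math.nan
    return (field - tree) / total


def crop_index_series(
    counts: dict[str, dict[str, int]],
    durations: dict[str, tuple[float, float]],
    grid: np.ndarray,
) -> TimeSeries:
    """Per-phase crop index painted onto a grid; NaN in gaps and empty phases.

    ``counts`` maps phase -> {"tree": n, "field": n, ...}.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.full_like(grid, np.nan)
    for phase, cc in counts.items():
        if phase not in durations:
            continue
        idx = crop_index(int(cc.get("tree", 0)), int(cc.get("field", 0)))
        start, end = durations[phase]
        covered = (grid >= end) & (grid <= start)
        values[covered] = idx
    return TimeSeries(grid, values, kind="crop_index")


def resample_to_grid(ts: TimeSeries, grid: np.ndarray) -> TimeSeries:
    """Resample a series onto a (descending) target grid by linear interpolation.

    Step-function series already defined on a finer grid are effectively
    sampled; the target grid must lie within the source support.
    """
    grid = np.asarray(grid, dtype=float)
    src_old, src_young = ts.grid[0], ts.grid[-1]
    if grid.max() > src_old or grid.min() < src_young:
        raise ValueError("target grid extends beyond the series support")
    # np.interp needs ascending x
    values = np.interp(grid[::-1], ts.grid[::-1], ts.values[::-1])[::-1]
    return TimeSeries(grid, values, kind=ts.kind)


def proxy_correlation(a: TimeSeries, b: TimeSeries) -> tuple[float, float, float]:
    """Pearson correlation between two proxies on the same grid.

    Returns (r, r^2, p) with the two-sided p-value from
    t = r sqrt((n-2)/(1-r^2)). Pairs with NaN in either series are dropped.
    Returns (nan, nan, nan) when either series has zero variance.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("series must share the same grid")
    ok = np.isfinite(a.values) & np.isfinite(b.values)
    x, y = a.values[ok], b.values[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(r) ** 2, float(p))


def correlation_matrix(series: dict[str, TimeSeries]) -> pd.DataFrame:
    """Pairwise r / r^2 / p for a set of proxies on a common grid (long format)."""
    names = list(series)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            r, r2, p = proxy_correlation(series[na], series[nb])
            rows.append({"proxy_a": na, "proxy_b": nb, "r": r, "r2": r2, "p": p})
    return pd.DataFrame(rows)
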