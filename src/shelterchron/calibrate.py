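"""Single-date radiocarbon calibration and posterior summaries.

Calibration turns a lab determination r +/- sigma into a normalized posterior
over calendar age theta on a regular grid, using an error-in-variables
Gaussian likelihood against the calibration curve:

    p(theta) ∝ exp(-(r - mu(theta))^2 / (2 (sigma^2 + sigma_c(theta)^2)))
               / sqrt(sigma^2 + sigma_c(theta)^2)

The 1/sqrt(total variance) prefactor is included so that curve segments with
inflated uncertainty are not over-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from shelterchron.calcurve import CalibrationCurve, curve_at

CONTEXT_STATUSES = ("intact", "disturbed", "missing_provenience", "pre_occupation", "modern")
CROP_CATEGORIES = ("tree", "field", "other", "none")

#: default reporting level, the conventional 2-sigma range
TWO_SIGMA = 0.954


@dataclass(frozen=True)
class RadiocarbonDate:
    """One lab determination with its excavation context."""

    lab_id: str
    c14_age: float
    c14_sigma: float
    material: str = ""
    taxon: str = ""
    crop_category: str = "none"
    unit: str = ""
    stratum: str = ""
    level: str = ""
    context_status: str = "intact"
    phase_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.c14_age):
            raise ValueError(f"{self.lab_id}: non-finite 14C age")
        if not (self.c14_sigma > 0):
            raise ValueError(f"{self.lab_id}: 14C sigma must be > 0")
        if self.context_status not in CONTEXT_STATUSES:
            raise ValueError(f"{self.lab_id}: unknown context_status {self.context_status!r}")
        if self.crop_category not in CROP_CATEGORIES:
            raise ValueError(f"{self.lab_id}: unknown crop_category {self.crop_category!r}")


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized posterior over calendar age on a regular ascending grid.

    ``mass`` is probability mass per cell (sums to one); ``truncated`` flags
    posteriors with non-negligible mass at the grid edges.
    """

    grid: np.ndarray
    mass: np.ndarray
    truncated: bool = field(default=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1:
            raise ValueError("grid and mass must be equal-length 1-D arrays")
        if np.any(mass < 0):
            raise ValueError("negative probability mass")
        total = mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"mass must sum to 1 (got {total})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    step: float = 5.0,
    grid: np.ndarray | None = None,
    edge_tol: float = 1e-6,
) -> CalibratedDensity:
    """Calibrate one radiocarbon date against a curve.

    Parameters
    ----------
    step : float
        Grid resolution in calendar years; default 5.
    grid : ndarray, optional
        Explicit evaluation grid (ascending, within the curve support). By
        default the full curve support is used.
    edge_tol : float
        If, after normalization, mass at either edge cell exceeds this the
        result is flagged ``truncated``.
    """
    if grid is None:
        lo, hi = curve.support
        grid = np.arange(lo, hi + 0.5 * step, step, dtype=float)
    else:
        grid = np.asarray(grid, dtype=float)
    mu, sig_c = curve_at(curve, grid)
    var = date.c14_sigma**2 + sig_c**2
    resid = date.c14_age - mu
    # log-space for numerical safety far out in the tails
    logw = -0.5 * resid**2 / var - 0.5 * np.log(var)
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{date.lab_id}: calibration produced zero mass")
    mass = w / total
    truncated = bool(mass[0] > edge_tol or mass[-1] > edge_tol)
    return CalibratedDensity(grid, mass, truncated=truncated)


def mean_intercept(d: CalibratedDensity) -> float:
    """Probability-weighted mean calendar age of a calibrated density.

    This point summary is what the event-density estimate treats as the
    event location of a dated sample.
    """
    return float(np.sum(d.grid * d.mass))


def hpd(d: CalibratedDensity, level: float = TWO_SIGMA) -> list[tuple[float, float]]:
    """Highest-posterior-density region as [older, younger] intervals.

    Greedily accumulates the highest-mass grid cells until coverage reaches
    ``level``, then merges selected cells into contiguous runs. Ties at the
    cutoff are broken toward the older cell, so the result is deterministic.
    Intervals are returned oldest-first as (older_edge, younger_edge) pairs
    at grid resolution.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    # sort by mass descending; among equal masses prefer the older (larger) age
    order = np.lexsort((-d.grid, -d.mass))
    csum = np.cumsum(d.mass[order])
    # tiny slack so 0.5 + 0.3 >= 0.8 despite float rounding
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, d.grid.size)
    chosen = np.sort(order[:k])
    # merge contiguous runs of selected cell indices
    breaks = np.where(np.diff(chosen) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [chosen.size - 1]))
    intervals = [
        (float(d.grid[chosen[e]]), float(d.grid[chosen[s]]))  # older, younger
        for s, e in zip(starts, ends)
    ]
    intervals.sort(key=lambda iv: -iv[0])
    return intervals


def round_range_outward(interval: tuple[float, float], to: float = 5.0) -> tuple[float, float]:
    """Round a reported (older, younger) range outward to the nearest ``to`` years."""
    older, younger = interval
    return (float(np.ceil(older / to) * to), float(np.floor(younger / to) * to))


def read_dates_csv(path: str | Path) -> list[RadiocarbonDate]:
    """Read a dates table CSV into RadiocarbonDate records.

    Required columns: lab_id, c14_age_bp, c14_error, material, taxon,
    crop_category, unit, stratum, level, context_status; phase_label optional.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "lab_id", "c14_age_bp", "c14_error", "material", "taxon",
        "crop_category", "unit", "stratum", "level", "context_status",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dates = []
    for row in df.itertuples(index=False):
        dates.append(
            RadiocarbonDate(
                lab_id=row.lab_id,
                c14_age=float(row.c14_age_bp),
                c14_sigma=float(row.c14_error),
                material=row.material,
                taxon=row.taxon,
                crop_category=row.crop_category or "none",
                unit=row.unit,
                stratum=row.stratum,
                level=row.level,
                context_status=row.context_status,
                phase_label=(getattr(row, "phase_label", "") or None),
            )
        )
    return dates


def write_dates_csv(dates: list[RadiocarbonDate], path: str | Path) -> None:
    """Write a dates table in the CSV dialect read_dates_csv consumes."""
    df = pd.DataFrame(
        {
            "lab_id": [d.lab_id for d in dates],
            "c14_age_bp": [d.c14_age for d in dates],
            "c14_error": [d.c14_sigma for d in dates],
            "material": [d.material for d in dates],
            "taxon": [d.taxon for d in dates],
            "crop_category": [d.crop_category for d in dates],
            "unit": [d.unit for d in dates],
            "stratum": [d.stratum for d in dates],
            "level": [d.level for d in dates],
            "context_status": [d.context_status for d in dates],
            "phase_label": [d.phase_label or "" for d in dates],
        }
    )
    df.to_csv(path, index=False)
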