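"""Sedimentation and botanical depositional-rate models.

A stratum's sedimentation rate is the summed mean thickness of that stratum
across excavation units divided by the minimum bounding span of the
radiocarbon-dated events originating within it:

    s = (sum_i z_i) / d

Site-wide rate at time t (S_t) sums s over every stratum whose dated span
contains t — strata at a multi-use site overlap in time, so the summation is
over all covering spans. Botanical depositional rates follow the same logic,
except counts and durations come from the modelled chronological phases,
which by construction do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from shelterchron.event_density import TimeSeries

logger = logging.getLogger(__name__)

CORNERS = ("NE", "NW", "SE", "SW")


class SpanError(ValueError):
    """A stratum's dated span is undefined (fewer than 2 dated events)."""


@dataclass(frozen=True)
class StratumSpan:
    """Minimum bounding span of dated events within one stratum."""

    stratum: str
    oldest: float
    youngest: float

    def __post_init__(self) -> None:
        if self.oldest < self.youngest:
            raise ValueError(f"{self.stratum}: oldest must be >= youngest")

    @property
    def d(self) -> float:
        """Span length in years."""
        return self.oldest - self.youngest

    def contains(self, t: float) -> bool:
        """Closed-interval membership test (boundary t counts as covered)."""
        return self.youngest <= t <= self.oldest


def read_thickness_csv(path: str | Path) -> pd.DataFrame:
    """Read a stratum-thickness table (unit, stratum, corner, thickness_cm)."""
    df = pd.read_csv(path, dtype={"unit": str, "stratum": str, "corner": str})
    required = {"unit", "stratum", "corner", "thickness_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["thickness_cm"] < 0).any():
        raise ValueError(f"{path}: negative thickness")
    bad = ~df["corner"].isin(CORNERS)
    if bad.any():
        raise ValueError(f"{path}: unknown corner labels {sorted(df.loc[bad, 'corner'].unique())}")
    counts = df.groupby(["unit", "stratum"])["corner"].count()
    if (counts > 4).any():
        raise ValueError(f"{path}: more than 4 corners for some (unit, stratum)")
    return df


def mean_stratum_thickness(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean corner thickness per (unit, stratum), in cm.

    Units where a stratum pinches out to zero thickness are legal.
    """
    return table.groupby(["unit", "stratum"])["thickness_cm"].mean()


def stratum_span(events, stratum: str = "") -> StratumSpan:
    """Minimum bounding span of dated-event ages (mean intercepts) in a stratum.

    Raises
    ------
    SpanError
        With fewer than 2 events the span is undefined and the stratum is
        excluded from rate calculations.
    """
    ages = np.asarray(list(events), dtype=float)
    if ages.size < 2:
        raise SpanError(f"stratum {stratum or '?'}: span undefined with {ages.size} dated event(s)")
    return StratumSpan(stratum=stratum, oldest=float(ages.max()), youngest=float(ages.min()))


def sedimentation_rate(mean_thicknesses, span: StratumSpan) -> float:
    """Stratum sedimentation rate in cm/year: summed mean thickness over span.

    Raises
    ------
    SpanError
        If the span is degenerate (d == 0).
    """
    z_sum = float(np.sum(np.asarray(list(mean_thicknesses), dtype=float)))
    if span.d <= 0:
        raise SpanError(f"stratum {span.stratum}: zero-length span, rate undefined")
    return z_sum / span.d


def sitewide_rate(strata: list[tuple[float, StratumSpan]], grid: np.ndarray) -> TimeSeries:
    """Site-wide sedimentation rate S_t on a grid.

    S_t sums the per-stratum rates of every stratum whose dated span contains
    t (closed at both ends); times covered by no stratum get 0.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for rate, span in strata:
        covered = (grid >= span.youngest) & (grid <= span.oldest)
        values[covered] += rate
    return TimeSeries(grid, values, kind="sedimentation")


# --- specimen-to-phase assignment -----------------------------------------

UNASSIGNED = "unassigned"
UNASSIGNED_AMBIGUOUS = "unassigned-ambiguous"


def read_botanical_csv(path: str | Path) -> pd.DataFrame:
    """Read a botanical specimen table (specimen_id, taxon, crop_category, unit, stratum, level)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"specimen_id", "taxon", "crop_category", "unit", "stratum", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_concordance(path: str | Path) -> dict:
    """Read a stratum -> phase concordance (YAML).

    Each stratum maps either to a phase name, or — for strata spanning more
    than one phase — to ``{"levels": {level: phase, ...}}`` so assignment can
    fall back on the recorded excavation level.
    """
    with open(path, encoding="utf-8") as fh:
        conc = yaml.safe_load(fh)
    if not isinstance(conc, dict):
        raise ValueError(f"{path}: concordance must be a mapping")
    return conc


def assign_specimens_to_phases(
    assemblage: pd.DataFrame,
    concordance: dict,
    durations: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Assign each botanical specimen to a chronological phase by context.

    A stratum mapped to a single phase assigns directly. A stratum spanning
    several phases consults a per-level sub-map; specimens without a usable
    level there become ``unassigned-ambiguous`` rather than being guessed.
    Specimens from unmapped strata are ``unassigned``. Counts are conserved:
    assigned + unassigned == total.

    Returns the assemblage with added ``phase``, ``interval_start`` and
    ``interval_end`` columns (the phase's mean modelled boundaries).
    """
    phases = []
    for row in assemblage.itertuples(index=False):
        entry = concordance.get(row.stratum)
        if entry is None:
            phases.append(UNASSIGNED)
        elif isinstance(entry, str):
            phases.append(entry)
        elif isinstance(entry, dict):
            sub = entry.get("levels", {})
            phases.append(sub.get(row.level, UNASSIGNED_AMBIGUOUS))
        else:
            raise ValueError(f"bad concordance entry for stratum {row.stratum!r}")
    out = assemblage.copy()
    out["phase"] = phases
    out["interval_start"] = [durations.get(p, (np.nan, np.nan))[0] for p in phases]
    out["interval_end"] = [durations.get(p, (np.nan, np.nan))[1] for p in phases]
    n_unassigned = sum(p.startswith("unassigned") for p in phases)
    logger.info("assigned %d specimens, %d unassigned", len(phases) - n_unassigned, n_unassigned)
    return out


def botanical_rate(
    counts: dict[str, int],
    durations: dict[str, tuple[float, float]],
    grid: np.ndarray,
) -> TimeSeries:
    """Botanical depositional rate (specimens/year) painted onto a grid.

    Within a phase's [mean start, mean end] interval the rate is
    count / duration; occupation gaps get 0. Phases never overlap, so no
    cross-phase summation arises.

    Raises
    ------
    ValueError
        If a phase has specimens but zero (or missing) duration.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for phase, count in counts.items():
        if count == 0:
            continue
        if phase not in durations:
            raise ValueError(f"phase {phase!r} has {count} specimens but no duration")
        start, end = durations[phase]
        dur = start - end
        if dur <= 0:
            raise ValueError(f"phase {phase!r}: nonzero count with zero duration")
        covered = (grid >= end) & (grid <= start)
        values[covered] += count / dur
    return TimeSeries(grid, values, kind="botanical_rate")
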