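"""Radiocarbon calibration curves: reading, synthesis, and interpolation.

A calibration curve tabulates the expected conventional radiocarbon age
(with a 1-sigma curve uncertainty) as a function of calendar age. Files in
the IntCal text convention list calendar ages descending with ``#`` comment
lines; internally the grid is always stored ascending in cal BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class CurveError(ValueError):
    """Malformed or invalid calibration-curve data."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Tabulated mapping from calendar age (cal BP) to radiocarbon age.

    Attributes
    ----------
    cal_bp : ndarray
        Calendar-age knots in years BP, strictly ascending.
    c14_age : ndarray
        Conventional radiocarbon age (years BP) at each knot.
    sigma_curve : ndarray
        1-sigma curve uncertainty in radiocarbon years, positive everywhere
        (zero permitted only for synthetic oracle curves).
    name : str
        Free-text label.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma_curve: np.ndarray
    name: str = field(default="unnamed")

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_bp, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.sigma_curve, dtype=float)
        if not (cal.shape == c14.shape == sig.shape) or cal.ndim != 1:
            raise CurveError("curve columns must be 1-D and of equal length")
        if cal.size < 2:
            raise CurveError("curve needs at least 2 knots")
        order = np.argsort(cal, kind="stable")
        cal, c14, sig = cal[order], c14[order], sig[order]
        if np.any(np.diff(cal) <= 0):
            raise CurveError("duplicate cal BP knots in curve")
        if np.any(sig < 0):
            raise CurveError("negative curve sigma")
        if not (np.all(np.isfinite(cal)) and np.all(np.isfinite(c14)) and np.all(np.isfinite(sig))):
            raise CurveError("non-finite values in curve")
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "sigma_curve", sig)

    @property
    def support(self) -> tuple[float, float]:
        """(youngest, oldest) cal BP covered by the curve."""
        return float(self.cal_bp[0]), float(self.cal_bp[-1])


def read_curve(path: str | Path, dialect: str = "intcal-text", name: str | None = None) -> CalibrationCurve:
    """Read a calibration curve from an IntCal-style text file or CSV.

    Lines starting with ``#`` are comments. The first three numeric columns
    are (cal BP, 14C age BP, 1 sigma); extra columns are ignored. Rows may be
    in either order; the returned curve is ascending in cal BP.

    Raises
    ------
    CurveError
        On a malformed row (the message names the 1-based line number) or on
        duplicate cal BP values.
    """
    if dialect not in ("intcal-text", "csv"):
        raise ValueError(f"unknown curve dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            # tolerate a CSV header row in csv dialect
            if dialect == "csv" and lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue
            if len(parts) < 3:
                raise CurveError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                vals = (float(parts[0]), float(parts[1]), float(parts[2]))
            except ValueError as exc:
                raise CurveError(f"{path}: line {lineno}: non-numeric field") from exc
            rows.append(vals)
    if len(rows) < 2:
        raise CurveError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows, dtype=float)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name or path.stem)


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Write a curve as comma-separated IntCal-style text (round-trip exact)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# calibration curve: {curve.name}\n")
        fh.write("# cal_bp,c14_age_bp,sigma\n")
        for cal, c14, sig in zip(curve.cal_bp, curve.c14_age, curve.sigma_curve):
            fh.write(f"{float(cal)!r},{float(c14)!r},{float(sig)!r}\n")


def make_linear_curve(start: float, end: float, step: float, sigma: float, name: str = "identity") -> CalibrationCurve:
    """Synthesize an identity curve mu(theta) = theta on [start, end].

    Useful as a closed-form oracle: under it a date r +/- s calibrates to a
    Gaussian posterior centred on r. ``sigma`` of zero is allowed for exact
    oracle tests only.
    """
    if start >= end:
        raise ValueError("start must be < end")
    if step <= 0:
        raise ValueError("step must be positive")
    if step >= end - start:
        raise ValueError("step must be smaller than the curve span")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    cal = np.arange(start, end + 0.5 * step, step, dtype=float)
    return CalibrationCurve(cal, cal.copy(), np.full_like(cal, float(sigma)), name=name)


def curve_at(curve: CalibrationCurve, theta: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate (mu, sigma) at calendar age(s) ``theta``.

    Raises
    ------
    ValueError
        If any theta lies outside the curve support.
    """
    t = np.asarray(theta, dtype=float)
    lo, hi = curve.support
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"theta outside curve support [{lo}, {hi}]")
    mu = np.interp(t, curve.cal_bp, curve.c14_age)
    sig = np.interp(t, curve.cal_bp, curve.sigma_curve)
    return mu, sig
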