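"""Amplification-efficiency calibration from serial-dilution standard curves.

Ct is regressed on log10(relative template input); for an ideal reaction the
template doubles every cycle, so the slope is -1/log10(2) = -3.3219 cycles
per decade and the efficiency

    E = (10 ** (-1 / slope) - 1) * 100   [percent]

equals 100.  Primer pairs are accepted when E falls inside a window,
by convention the closed interval [90, 110] percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyFit",
    "InvalidCurveError",
    "fit_standard_curve",
    "classify_efficiency",
    "load_dilution_csv",
    "SEA_URCHIN_EFFICIENCIES",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = (90.0, 110.0)

#: Published efficiencies (%) and R^2 of the sea-urchin primer panel used
#: throughout the worked examples (printed calibration results; the raw
#: dilution Ct values behind them were not published).
SEA_URCHIN_EFFICIENCIES: dict[str, tuple[float, float]] = {
    "28S": (94.0, 0.997),
    "Cycb": (91.0, 0.996),
    "Daglb-2": (98.4, 0.995),
    "Ebr1": (90.1, 1.000),
    "GAPDH": (105.2, 0.991),
    "Hmg1": (101.9, 0.999),
    "Smtnl1": (92.0, 1.000),
    "Ubb": (92.5, 0.999),
}


class InvalidCurveError(ValueError):
    """The dilution series does not describe a usable standard curve."""


@dataclass(frozen=True)
class DilutionSeries:
    """One primer pair's serial dilution: (relative input d, Ct replicates).

    ``points`` maps each dimensionless input amount (1, 1/2, 1/4, ...) to a
    tuple of replicate Ct values.  Inputs must be positive, distinct and
    monotone; at least three points are required for a regression.
    """

    gene: str
    points: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self):
        ds = [d for d, _ in self.points]
        if len(ds) < 3:
            raise InvalidCurveError("need at least 3 dilution points")
        if any(d <= 0 for d in ds):
            raise InvalidCurveError("dilution amounts must be positive")
        diffs = np.diff(ds)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InvalidCurveError(
                "dilution amounts must be strictly increasing or decreasing"
            )
        for d, reps in self.points:
            if len(reps) == 0:
                raise InvalidCurveError(f"dilution point {d} has no Ct replicates")

    @classmethod
    def from_records(
        cls, gene: str, records: Iterable[tuple[float, float]]
    ) -> "DilutionSeries":
        """Build from (dilution, ct) pairs, grouping replicates by dilution."""
        by_d: dict[float, list[float]] = {}
        for d, ct in records:
            by_d.setdefault(float(d), []).append(float(ct))
        pts = tuple(
            (d, tuple(by_d[d])) for d in sorted(by_d, reverse=True)
        )
        return cls(gene=gene, points=pts)


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: slope/intercept of Ct ~ log10(input), E% and R^2."""

    gene: str
    slope: float
    intercept: float
    efficiency: float  # percent; 100 = perfect doubling
    r_squared: float
    passed: bool
    window: tuple[float, float] = DEFAULT_WINDOW
    reason: str = "within window"

    @property
    def base(self) -> float:
        """Per-cycle amplification factor, 1 + E/100 (2.0 at E = 100%)."""
        return 1.0 + self.efficiency / 100.0

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "slope": self.slope,
            "intercept": self.intercept,
            "efficiency_pct": self.efficiency,
            "r_squared": self.r_squared,
            "passed": self.passed,
            "window": list(self.window),
            "reason": self.reason,
        }


def fit_standard_curve(
    series: DilutionSeries,
    window: tuple[float, float] = DEFAULT_WINDOW,
    collapse_replicates: bool = True,
) -> EfficiencyFit:
    """Ordinary least squares of Ct on log10(relative input).

    Replicate Ct values within a dilution point are averaged before the
    regression by default (``collapse_replicates=False`` fits on the raw
    replicates instead).  A slope >= 0 — Ct not decreasing with more
    template — is rejected as an invalid curve.
    """
    if collapse_replicates:
        x = np.log10([d for d, _ in series.points])
        y = np.array([float(np.mean(reps)) for _, reps in series.points])
    else:
        x = np.log10(
            np.concatenate([[d] * len(reps) for d, reps in series.points])
        )
        y = np.concatenate([reps for _, reps in series.points]).astype(float)
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise InvalidCurveError(
            f"slope {res.slope:.3f} >= 0: Ct does not decrease with input"
        )
    eff = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    r2 = float(res.rvalue**2)
    passed, reason = classify_efficiency(eff, window)
    return EfficiencyFit(
        gene=series.gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(eff),
        r_squared=r2,
        passed=passed,
        window=tuple(window),
        reason=reason,
    )


def classify_efficiency(
    efficiency: float | EfficiencyFit,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[bool, str]:
    """Accept/reject an efficiency against a closed percent window.

    Boundary values pass (the window is a closed interval).
    """
    if isinstance(efficiency, EfficiencyFit):
        efficiency = efficiency.efficiency
    low, high = window
    if not (0 < low <= high):
        raise ValueError(f"invalid window {window!r}")
    if efficiency < low:
        return False, "below window"
    if efficiency > high:
        return False, "above window"
    return True, "within window"


def load_dilution_csv(path: str | Path) -> list[DilutionSeries]:
    """Read dilution series from a CSV with columns gene, dilution, replicate, ct."""
    df = pd.read_csv(path)
    required = {"gene", "dilution", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(sorted(missing))}")
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        out.append(
            DilutionSeries.from_records(
                str(gene), zip(sub["dilution"], sub["ct"])
            )
        )
    return out


def fits_to_frame(fits: Sequence[EfficiencyFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])


def fits_to_json(fits: Sequence[EfficiencyFit], path: str | Path | None = None) -> str:
    text = json.dumps([f.to_dict() for f in fits], indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
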