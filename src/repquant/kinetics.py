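"""Washout kinetics and small expression-ratio computations.

Carboxyhaemoglobin (CO-Hb) washout after a carbon-monoxide exposure declines
linearly back to an endogenous baseline.  ``fit_washout`` fits an ordinary
least-squares line to the above-baseline points and reports the washout
half-life, defined on the above-baseline saturation under the linear model:
the time for S(t) − baseline to fall to half its starting value,

    half_life = (S0 − baseline) / (2 · |slope|),

with S0 the fitted saturation at the first time point of the series.  This
definition is invariant to relabeling the time origin.

Also provided: housekeeping-normalized relative expression (RT-qPCR style),
fold changes, and the tagging-fraction ratio used to compare pharmacological
versus hypoxic reporter-cell tagging efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WashoutSeries",
    "WashoutFit",
    "ExpressionMeasurement",
    "TaggingFraction",
    "fit_washout",
    "relative_expression",
    "fold_change",
    "tagging_fraction",
]


@dataclass
class WashoutSeries:
    """CO-Hb washout time series: times in minutes, saturations in %."""

    times_min: np.ndarray
    saturations_pct: np.ndarray
    baseline_pct: float
    baseline_sd_pct: float = 0.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.saturations_pct = np.asarray(self.saturations_pct, dtype=float)
        if self.times_min.shape != self.saturations_pct.shape:
            raise ValueError("times and saturations must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.saturations_pct < 0) | (self.saturations_pct > 100)):
            raise ValueError("saturations must lie in [0, 100] %")


@dataclass
class WashoutFit:
    slope_pct_per_min: float
    intercept_pct: float  # fitted value at t = 0
    s0_pct: float  # fitted value at the first time point of the series
    r_squared: float
    half_life_min: float
    n_points_used: int


@dataclass
class ExpressionMeasurement:
    """Target quantity normalized to a housekeeping ribosomal-protein mRNA
    (S12 or L28)."""

    target_quantity: float
    housekeeping_quantity: float
    housekeeping_name: str = "L28"


@dataclass
class TaggingFraction:
    percent: float
    percent_rounded: int  # nearest integer, for report text


def fit_washout(series: WashoutSeries) -> WashoutFit:
    """OLS line through the above-baseline washout points, plus half-life.

    Points at or below baseline + baseline_sd are excluded (they sit on the
    clamp, not the decline).  Requires at least 3 usable points and a
    negative slope.
    """
    cut = series.baseline_pct + series.baseline_sd_pct
    usable = series.saturations_pct > cut
    t = series.times_min[usable]
    s = series.saturations_pct[usable]
    if t.size < 3:
        raise ValueError(
            f"only {t.size} points above baseline; at least 3 required"
        )
    slope, intercept = np.polyfit(t, s, 1)
    if slope >= 0:
        raise ValueError("no washout: fitted slope is non-negative")
    pred = intercept + slope * t
    ss_res = float(np.sum((s - pred) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s0 = float(intercept + slope * t[0])
    half_life = (s0 - series.baseline_pct) / (2.0 * abs(slope))
    if half_life <= 0:
        raise ValueError("no washout: fitted start is not above baseline")
    return WashoutFit(
        slope_pct_per_min=float(slope), intercept_pct=float(intercept),
        s0_pct=s0, r_squared=r2, half_life_min=float(half_life),
        n_points_used=int(t.size),
    )


def relative_expression(m: ExpressionMeasurement) -> float:
    """Target mRNA quantity relative to its housekeeping reference."""
    if m.housekeeping_quantity <= 0:
        raise ValueError("housekeeping quantity must be positive")
    return m.target_quantity / m.housekeeping_quantity


def fold_change(a: float, b: float) -> float:
    """Ratio of a quantity to a reference quantity (b > 0)."""
    if b <= 0:
        raise ValueError("reference quantity must be positive")
    return a / b


def tagging_fraction(
    tagged_condition: float, tagged_reference: float
) -> TaggingFraction:
    """Tagged cells per mouse under a condition, as a percent of a reference.

    E.g. pharmacological (HIF-stabilizer) tagging relative to hypoxic tagging.
    The raw percent is always stored; the nearest-integer rounding is only a
    report-text convention.
    """
    if tagged_reference <= 0:
        raise ValueError("reference count must be positive")
    pct = 100.0 * tagged_condition / tagged_reference
    return TaggingFraction(percent=pct, percent_rounded=int(round(pct)))
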