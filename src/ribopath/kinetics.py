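"""Translation kinetics from continuous luciferase recordings, plus
median-effect dose-response fitting and the combination index.

Full-translation time (FTT) is the time at which reporter activity first
becomes detectable in a continuously recorded translation reaction; it grows
with the time the pre-initiation complex spends scanning the 5' UTR. Drug
interaction is quantified with the Chou-Talalay combination index on
median-effect fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LucCurve",
    "MedianEffectFit",
    "SynergyResult",
    "NoOnsetError",
    "estimate_ftt",
    "ftt_linearity",
    "endpoint_fold_inhibition",
    "median_effect_fit",
    "combination_index",
]


class NoOnsetError(ValueError):
    """The recording never rises above baseline: no detectable translation."""


@dataclass
class LucCurve:
    """A time-stamped luminescence recording."""

    times: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray  # RLU
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size != self.signal.size:
            raise ValueError("times and signal lengths differ")
        if self.times.size < 5:
            raise ValueError("need >= 5 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


def estimate_ftt(
    curve: LucCurve,
    baseline_points: int = 3,
    sd_multiplier: float = 3.0,
    fit_points: int = 4,
) -> float:
    """Estimate full-translation time (minutes) from one recording.

    Detection threshold = mean + ``sd_multiplier`` * SD of the first
    ``baseline_points`` samples. Onset is the first time with two consecutive
    samples above threshold; the FTT is the x-intercept of a least-squares
    line through the first ``fit_points`` above-threshold samples from the
    onset, clamped to be no earlier than the last below-threshold time.

    Raises :class:`NoOnsetError` when the curve never exceeds threshold.
    """
    t = curve.times
    y = curve.signal
    base = y[:baseline_points]
    threshold = base.mean() + sd_multiplier * base.std(ddof=0)
    above = y > threshold
    onset_idx = None
    for i in range(baseline_points, above.size - 1):
        if above[i] and above[i + 1]:
            onset_idx = i
            break
    if onset_idx is None:
        raise NoOnsetError("signal never rises above baseline")
    k = min(fit_points, above.size - onset_idx)
    tt = t[onset_idx : onset_idx + k]
    yy = y[onset_idx : onset_idx + k]
    if k >= 2 and np.ptp(yy) > 0:
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope > 0:
            ftt = (threshold - intercept) / slope
        else:
            ftt = tt[0]
    else:
        ftt = tt[0]
    last_below = t[onset_idx - 1] if onset_idx > 0 else t[0]
    return float(max(ftt, last_below))


def ftt_linearity(
    curves: list[LucCurve],
    lengths: list[float],
    **ftt_kwargs,
) -> tuple[float, float]:
    """Least-squares slope and intercept of FTT versus 5' UTR length.

    On synthetic curves with onsets t0 + c * L the slope recovers c
    (minutes per nucleotide).
    """
    if len(curves) != len(lengths):
        raise ValueError("curves and lengths differ in number")
    distinct = set(lengths)
    if len(distinct) < 3:
        raise ValueError("need >= 3 distinct lengths")
    ftts = [estimate_ftt(c, **ftt_kwargs) for c in curves]
    slope, intercept = np.polyfit(np.asarray(lengths, float), ftts, 1)
    return float(slope), float(intercept)


def endpoint_fold_inhibition(signal_control: float, signal_treated: float) -> float:
    """Fold inhibition = control / treated endpoint signal."""
    if signal_control <= 0 or signal_treated <= 0:
        raise ValueError("signals must be positive")
    return signal_control / signal_treated


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: fa/(1-fa) = (d/Dm)^m."""

    Dm: float
    m: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.Dm <= 0 or self.m <= 0:
            raise ValueError("Dm and m must be positive")

    def effect(self, dose: float) -> float:
        """Affected fraction at a dose."""
        if dose < 0:
            raise ValueError("negative dose")
        if dose == 0:
            return 0.0
        r = (dose / self.Dm) ** self.m
        return r / (1.0 + r)

    def dose_for_effect(self, fa: float) -> float:
        """Dose producing affected fraction ``fa`` (0 < fa < 1)."""
        if not 0.0 < fa < 1.0:
            raise ValueError("fa must be in (0, 1)")
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def median_effect_fit(doses, affected_fractions) -> MedianEffectFit:
    """Fit the median-effect line log(fa/(1-fa)) = m log d - m log Dm.

    Points with fa outside (0, 1) or nonpositive dose are excluded with a
    warning; at least 3 usable points are required.
    """
    import warnings

    d = np.asarray(doses, dtype=float)
    fa = np.asarray(affected_fractions, dtype=float)
    usable = (d > 0) & (fa > 0) & (fa < 1)
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} point(s) with fa outside (0,1) "
            "or nonpositive dose"
        )
    d, fa = d[usable], fa[usable]
    if d.size < 3:
        raise ValueError("need >= 3 usable dose-effect points")
    x = np.log(d)
    y = np.log(fa / (1.0 - fa))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError("fitted slope m is nonpositive; not a dose response")
    dm = math.exp(-intercept / m)
    resid = float(np.sum((y - (m * x + intercept)) ** 2))
    return MedianEffectFit(Dm=dm, m=float(m), residual=resid)


@dataclass(frozen=True)
class SynergyResult:
    """Combination-index summary for one (d1, d2, fa) combination point."""

    d1: float
    d2: float
    D1: float
    D2: float
    CI: float


def combination_index(
    d1: float,
    d2: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fa_combined: float,
    cross_term: bool = False,
) -> SynergyResult:
    """Chou-Talalay combination index for a combination dose (d1, d2).

    D_i is the dose of agent i alone producing the combined effect
    ``fa_combined``; CI = d1/D1 + d2/D2 (mutually exclusive form), optionally
    plus the cross term d1*d2/(D1*D2). CI < 1 synergy, = 1 additivity,
    > 1 antagonism.
    """
    if not 0.0 < fa_combined < 1.0:
        raise ValueError("fa_combined must be in (0, 1)")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be nonnegative")
    D1 = fit1.dose_for_effect(fa_combined)
    D2 = fit2.dose_for_effect(fa_combined)
    ci = d1 / D1 + d2 / D2
    if cross_term:
        ci += (d1 * d2) / (D1 * D2)
    return SynergyResult(d1=d1, d2=d2, D1=D1, D2=D2, CI=ci)
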