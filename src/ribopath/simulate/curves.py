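"""Synthetic luminescence recordings and median-effect dose-response tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..kinetics import LucCurve

__all__ = ["CurveSimSpec", "gen_luc_curve", "gen_dose_response"]


@dataclass
class CurveSimSpec:
    """Parameters for one simulated continuous luciferase recording."""

    onset_time: float  # min
    rise_rate: float = 100.0  # RLU/min
    plateau: float = 5000.0  # RLU
    baseline_noise_sd: float = 0.0  # RLU
    sampling_interval: float = 3.0  # min
    duration: float = 90.0  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration <= self.onset_time:
            raise ValueError("duration must exceed onset_time")


def gen_luc_curve(spec: CurveSimSpec) -> tuple[LucCurve, float]:
    """Simulate one recording; returns (curve, true onset time).

    Signal is zero-mean noise before onset, then a linear rise capped at the
    plateau, with Gaussian noise of ``baseline_noise_sd`` throughout.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration + 1e-9, spec.sampling_interval)
    clean = np.where(
        times <= spec.onset_time,
        0.0,
        np.minimum(spec.rise_rate * (times - spec.onset_time), spec.plateau),
    )
    noise = (
        rng.normal(0.0, spec.baseline_noise_sd, size=times.size)
        if spec.baseline_noise_sd > 0
        else 0.0
    )
    curve = LucCurve(
        times=times,
        signal=clean + noise,
        metadata={"onset_time": spec.onset_time},
    )
    return curve, spec.onset_time


def gen_dose_response(
    Dm: float,
    m: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-effect table following fa/(1-fa) = (d/Dm)^m plus Gaussian noise.

    Zero dose gives fa = 0; noisy fractions are clipped to [0, 1]. Returns a
    DataFrame with columns dose, fa.
    """
    if Dm <= 0 or m <= 0:
        raise ValueError("Dm and m must be positive")
    d = np.asarray(doses, dtype=float)
    if (d < 0).any():
        raise ValueError("negative dose")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / Dm) ** m, 0.0)
    fa = ratio / (1.0 + ratio)
    if noise_sd > 0:
        fa = np.clip(fa + rng.normal(0.0, noise_sd, size=fa.shape), 0.0, 1.0)
    return pd.DataFrame({"dose": d, "fa": fa})
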