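"""Simulated polysome-profile absorbance traces.

A trace is a mixture of Gaussian peaks (40S, 60S, 80S, and one peak per
polysome species) over a linear baseline, with additive Gaussian noise and an
optional rigid shift of the elution coordinate (emulating run-to-run
alignment offsets).  The analytic polysomal fraction — the summed area of
the polysome peaks over the total peak area — is recorded as ground truth.

The default peak layout gives ~70% polysomal ribosomes, typical of
asynchronously proliferating cultured cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..polysome import ProfileTrace


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian peak: label in {40S, 60S, 80S, poly}, center, sd, area."""

    label: str
    center: float
    width: float
    area: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"peak {self.label}: width must be positive")
        if self.area < 0:
            raise ValueError(f"peak {self.label}: area must be non-negative")


DEFAULT_PEAKS = (
    PeakSpec("40S", 1.8, 0.22, 3.0),
    PeakSpec("60S", 2.6, 0.24, 4.0),
    PeakSpec("80S", 3.5, 0.28, 15.0),
    PeakSpec("poly", 5.2, 0.32, 20.0),
    PeakSpec("poly", 6.3, 0.38, 14.0),
    PeakSpec("poly", 7.4, 0.46, 11.0),
    PeakSpec("poly", 8.5, 0.55, 7.0),
)


@dataclass(frozen=True)
class TraceSimConfig:
    peak_specs: Sequence[PeakSpec] = DEFAULT_PEAKS
    baseline_slope: float = 0.02
    baseline_level: float = 0.0
    noise_sd: float = 0.1
    alignment_offset: float = 0.0
    n_points: int = 400
    x_range: tuple = (0.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        centers = [p.center for p in self.peak_specs]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("peak centers must be strictly increasing")
        if self.n_points < 50:
            raise ValueError("n_points must be at least 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gaussian(x: np.ndarray, center: float, sd: float, area: float) -> np.ndarray:
    return area / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sd) ** 2)


def mixture_absorbance(config: TraceSimConfig, x: np.ndarray,
                       include_baseline: bool = True) -> np.ndarray:
    """Noise-free generating mixture evaluated at positions ``x``."""
    y = np.zeros_like(x, dtype=float)
    for p in config.peak_specs:
        y += _gaussian(x, p.center + config.alignment_offset, p.width, p.area)
    if include_baseline:
        y += config.baseline_level + config.baseline_slope * (x - x[0])
    return y


def gen_trace(config: TraceSimConfig):
    """Generate (ProfileTrace, truth).

    Truth records each peak's parameters and the analytic polysomal fraction
    (area of "poly"-labeled peaks over total peak area).
    """
    from . import SyntheticTruth

    rng = np.random.default_rng(config.seed)
    x = np.linspace(*config.x_range, config.n_points)
    y = mixture_absorbance(config, x)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=x.size)
    trace = ProfileTrace(x, y, label="simulated")
    total = sum(p.area for p in config.peak_specs)
    poly = sum(p.area for p in config.peak_specs if p.label == "poly")
    if total <= 0:
        raise ValueError("total peak area must be positive")
    truth = SyntheticTruth(
        assay="trace",
        params={"polysomal_fraction_percent": 100.0 * poly / total,
                "alignment_offset": config.alignment_offset,
                "noise_sd": config.noise_sd,
                "baseline_slope": config.baseline_slope},
        tables={"peaks": pd.DataFrame(
            [(p.label, p.center, p.width, p.area) for p in config.peak_specs],
            columns=["label", "center", "width", "area"])},
    )
    return trace, truth
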