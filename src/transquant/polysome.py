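"""Polysome-profile quantification and fraction-wise qPCR normalization.

A sucrose-gradient absorbance trace (A254 against elution position) resolves
free subunits (40S, 60S), the 80S monosome, and polysomes.  The fraction of
ribosomes engaged in translation is quantified as

    % polysomal = 100 * AUC(polysome region) / AUC(whole trace)

with the polysome region starting at the first inter-peak minimum after the
80S peak.  Traces from different runs are aligned rigidly at their 80S peaks
before comparison.  Fraction-wise qPCR of gradient fractions is normalized to
an in vitro transcript (HBB2 by convention) spiked into every fraction before
RNA isolation, which corrects for fraction-to-fraction isolation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .stats import (DegenerateVarianceError, TestResult, paired_t_one_tailed,
                    welch_one_tailed)

__all__ = [
    "ProfileTrace",
    "PeakAnnotation",
    "PolysomeQuant",
    "FoldChangeResult",
    "TraceFormatError",
    "read_trace",
    "baseline_correct",
    "detect_peaks",
    "align_to_80s",
    "percent_polysomal",
    "fold_change_polysomal",
    "fraction_qpcr_distribution",
]


class TraceFormatError(ValueError):
    """Raised for malformed absorbance trace files."""


class PeakDetectionError(ValueError):
    """Raised when no usable peak structure is found (flat or failed run)."""


@dataclass
class ProfileTrace:
    """An A254 absorbance trace over a strictly increasing elution coordinate."""

    positions: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.shape != self.absorbance.shape:
            raise TraceFormatError("positions and absorbance differ in length")
        if self.positions.size < 50:
            raise TraceFormatError("trace needs at least 50 points")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.absorbance).all()):
            raise TraceFormatError("trace contains non-finite values")
        if not np.all(np.diff(self.positions) > 0):
            raise TraceFormatError("positions must be strictly increasing")


@dataclass(frozen=True)
class PeakAnnotation:
    """80S peak (mandatory) plus optional subunit peaks and polysome boundary."""

    i80s: int
    pos_80s: float
    polysome_boundary: float
    i40s: int | None = None
    i60s: int | None = None


@dataclass(frozen=True)
class PolysomeQuant:
    auc_total: float
    auc_polysomal: float

    @property
    def percent_polysomal(self) -> float:
        return 100.0 * self.auc_polysomal / self.auc_total


@dataclass(frozen=True)
class FoldChangeResult:
    ratio: float
    test: TestResult
    n_pairs: int


def read_trace(path: str | Path, label: str | None = None) -> ProfileTrace:
    """Read a two-column (position, A254) CSV/TSV; header auto-detected."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise TraceFormatError(f"cannot parse trace file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceFormatError("trace file must have two columns")
    first = df.iloc[0]
    try:
        float(first.iloc[0]), float(first.iloc[1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    try:
        pos = df.iloc[:, 0].astype(float).to_numpy()
        absb = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise TraceFormatError(f"non-numeric values in trace file {path}") from exc
    if np.isnan(pos).any() or np.isnan(absb).any():
        raise TraceFormatError(f"NaN values in trace file {path}")
    return ProfileTrace(pos, absb, label=label or Path(path).stem)


BaselineMethod = Literal["linear-endpoints", "rolling-min", "none"]


def baseline_correct(trace: ProfileTrace,
                     method: BaselineMethod = "linear-endpoints",
                     window_fraction: float = 0.1) -> ProfileTrace:
    """Subtract an estimated baseline and clip at zero.

    ``linear-endpoints`` fits a straight line through the first and last
    samples (recorder drift); ``rolling-min`` subtracts a running minimum over
    a window of ``window_fraction`` of the trace; ``none`` is the identity
    apart from the zero clip.
    """
    y = trace.absorbance
    if method == "linear-endpoints":
        # average a short window at each end so single noisy samples do not
        # tilt the whole baseline
        w = max(1, y.size // 100)
        base = np.interp(trace.positions,
                         [trace.positions[0], trace.positions[-1]],
                         [float(y[:w].mean()), float(y[-w:].mean())])
    elif method == "rolling-min":
        w = max(3, int(round(window_fraction * y.size)))
        base = (pd.Series(y).rolling(w, center=True, min_periods=1).min()
                .to_numpy())
    elif method == "none":
        base = np.zeros_like(y)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    corrected = np.clip(y - base, 0.0, None)
    meta = dict(trace.metadata, baseline=method)
    return ProfileTrace(trace.positions.copy(), corrected, trace.label, meta)


def detect_peaks(trace: ProfileTrace,
                 min_prominence: float | None = None,
                 monosome_window: float = 0.4,
                 smooth_window: int | None = None) -> PeakAnnotation:
    """Locate the 80S peak and the polysome boundary.

    The 80S monosome is identified as the most prominent local maximum whose
    position falls within the first ``monosome_window`` fraction of the
    elution range (gradient layouts put subunits and the monosome early).
    Ties go to the earlier peak.  The polysome boundary is the first local
    minimum after the 80S peak.  ``min_prominence`` defaults to 2% of the
    trace's dynamic range.

    Detection runs on a lightly smoothed copy of the trace (Savitzky-Golay,
    window ``smooth_window`` samples, default ~2% of the trace length) so
    recorder noise cannot spawn spurious extrema; quantification elsewhere
    always uses the unsmoothed absorbance.
    """
    y = trace.absorbance
    if smooth_window is None:
        smooth_window = max(5, 2 * (y.size // 100) + 1)
    if smooth_window >= 5 and y.size > smooth_window:
        if smooth_window % 2 == 0:
            smooth_window += 1
        y = savgol_filter(y, smooth_window, polyorder=2)
    dynamic_range = float(y.max() - y.min())
    if dynamic_range <= 1e-9 * max(1.0, abs(float(y.max()))):
        raise PeakDetectionError("flat trace: zero dynamic range")
    if min_prominence is None:
        min_prominence = 0.02 * dynamic_range
    peaks, props = find_peaks(y, prominence=min_prominence)
    if peaks.size == 0:
        raise PeakDetectionError("no peak above the prominence threshold")
    span = trace.positions[-1] - trace.positions[0]
    limit = trace.positions[0] + monosome_window * span
    in_window = peaks[trace.positions[peaks] <= limit]
    if in_window.size == 0:
        raise PeakDetectionError("no peak inside the monosome window")
    prom = props["prominences"][np.isin(peaks, in_window)]
    best = np.flatnonzero(prom == prom.max())[0]  # earlier peak wins ties
    i80 = int(in_window[best])

    # subunit peaks: the two most prominent maxima before the 80S, if any
    before = peaks[peaks < i80]
    i40 = i60 = None
    if before.size >= 2:
        pb = props["prominences"][np.isin(peaks, before)]
        order = before[np.argsort(pb)[::-1][:2]]
        i40, i60 = int(min(order)), int(max(order))
    elif before.size == 1:
        i60 = int(before[0])

    # minima must clear the same prominence bar, so noise dips on a peak
    # flank cannot masquerade as the inter-peak boundary
    minima, _ = find_peaks(-y, prominence=min_prominence)
    after = minima[minima > i80]
    if after.size == 0:
        raise PeakDetectionError("no local minimum after the 80S peak")
    boundary = float(trace.positions[int(after[0])])
    return PeakAnnotation(i80, float(trace.positions[i80]), boundary, i40, i60)


def align_to_80s(traces: Sequence[ProfileTrace], **peak_kwargs) -> list[ProfileTrace]:
    """Rigidly shift traces so every 80S peak coincides with the first trace's."""
    if not traces:
        return []
    annotations = [detect_peaks(t, **peak_kwargs) for t in traces]
    ref = annotations[0].pos_80s
    out = []
    for t, a in zip(traces, annotations):
        shift = ref - a.pos_80s
        out.append(ProfileTrace(t.positions + shift, t.absorbance.copy(),
                                t.label, dict(t.metadata, shift_80s=shift)))
    return out


def _auc_from(positions: np.ndarray, y: np.ndarray, start: float) -> float:
    """Trapezoid AUC over positions >= start, interpolating at the boundary."""
    if start <= positions[0]:
        return float(np.trapezoid(y, positions))
    if start >= positions[-1]:
        return 0.0
    y0 = float(np.interp(start, positions, y))
    mask = positions > start
    xs = np.concatenate(([start], positions[mask]))
    ys = np.concatenate(([y0], y[mask]))
    return float(np.trapezoid(ys, xs))


def percent_polysomal(trace: ProfileTrace,
                      annotation: PeakAnnotation | None = None,
                      boundary: float | None = None,
                      total_from: float | None = None) -> PolysomeQuant:
    """Split the trace AUC at the polysome boundary.

    ``boundary`` overrides the detected first-minimum-after-80S boundary
    (manual region placement).  ``total_from`` optionally starts the *total*
    integral at a given position (e.g. the 40S onset) instead of the trace
    start.
    """
    if boundary is None:
        if annotation is None:
            annotation = detect_peaks(trace)
        boundary = annotation.polysome_boundary
    if not (trace.positions[0] <= boundary <= trace.positions[-1]):
        raise ValueError("polysome boundary outside the trace range")
    start = trace.positions[0] if total_from is None else total_from
    total = _auc_from(trace.positions, trace.absorbance, start)
    if total <= 0:
        raise ValueError("total AUC is zero; cannot quantify")
    poly = _auc_from(trace.positions, trace.absorbance, boundary)
    return PolysomeQuant(total, poly)


def fold_change_polysomal(treated: Sequence[float], control: Sequence[float],
                          design: Literal["paired", "unpaired"] = "paired",
                          direction: str = "less") -> FoldChangeResult:
    """Treated/control fold change of percent-polysomal values with a p-value.

    Paired designs report the mean of per-pair ratios and a one-tailed paired
    t test; unpaired (or unequal-n) designs report the ratio of arm means and
    a one-tailed Welch test.  Identical paired arms (all differences exactly
    zero) are reported as t=0, p=0.5, the continuity limit of the paired test.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per arm")
    if design == "paired" and treated.size != control.size:
        design = "unpaired"
    if design == "paired":
        ratio = float(np.mean(treated / control))
        try:
            test = paired_t_one_tailed(treated, control, direction)
        except DegenerateVarianceError:
            if np.all(treated == control):
                test = TestResult("paired_t_one_tailed", 0.0,
                                  treated.size - 1, 0.5, treated.size, direction)
            else:
                raise
    else:
        ratio = float(np.mean(treated) / np.mean(control))
        test = welch_one_tailed(treated, control, direction)
    return FoldChangeResult(ratio, test, min(treated.size, control.size))


def fraction_qpcr_distribution(ct: pd.DataFrame,
                               spike_target: str = "HBB2",
                               efficiency: float = 2.0) -> pd.DataFrame:
    """Spike-normalized percent-of-total distribution across gradient fractions.

    ``ct`` is a long table (fraction, target, ct).  Per fraction f the
    relative amount of a target is E**-(Ct_f - CtSpike_f); each target is then
    reported as percent of its own total over fractions, so rows sum to 100.
    """
    required = {"fraction", "target", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("non-finite Ct values")
    spike = ct[ct["target"] == spike_target].set_index("fraction")["ct"]
    targets = ct[ct["target"] != spike_target]
    missing = set(targets["fraction"]) - set(spike.index)
    if missing:
        raise ValueError(f"no spike Ct for fractions {sorted(missing)}")
    amounts = targets.assign(
        amount=lambda d: efficiency ** -(d["ct"].to_numpy()
                                         - spike.loc[d["fraction"]].to_numpy()))
    wide = amounts.pivot_table(index="target", columns="fraction",
                               values="amount", aggfunc="sum")
    return wide.div(wide.sum(axis=1), axis=0) * 100.0
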