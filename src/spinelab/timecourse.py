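"""Spine-volume dF/F0 time courses, phase-window averages and size correction.

Spine volume during structural LTP is tracked as the summed ROI fluorescence
of a cytosolic marker, normalized to its pre-stimulus baseline:
dF/F0 = (F - F0)/F0 with F0 the mean of the first 5-7 pre-stimulus points.
Time courses are summarized by averaging over named phase windows (e.g.
transient 1-3 min, sustained 9-11 / 12-15 / 15-20 min after uncaging onset).
Expansion-microscopy measurements are rescaled by an expansion factor
computed from nuclei areas before/after gel expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateBaselineError,
    EmptyWindowError,
    InvalidParameterError,
)

__all__ = [
    "RoiTrace",
    "PhaseWindows",
    "delta_f_over_f",
    "phase_averages",
    "expansion_correct",
    "TRANSIENT_SUSTAINED_WINDOWS",
]

#: Default phase windows (minutes from uncaging onset): transient and two
#: sustained phases.
TRANSIENT_SUSTAINED_WINDOWS: list[tuple[str, float, float]] = [
    ("transient", 1.0, 3.0),
    ("sustained_9_11", 9.0, 11.0),
    ("sustained_12_15", 12.0, 15.0),
]


@dataclass(frozen=True)
class RoiTrace:
    """A fluorescence time series for one ROI and channel.

    ``times`` are in seconds (or minutes for phase-window analyses — the
    caller keeps units consistent); ``f`` is the summed ROI fluorescence in
    arbitrary units.  ``baseline_n`` counts the leading pre-stimulus points
    used for F0.
    """

    times: np.ndarray
    f: np.ndarray
    channel: str = ""
    baseline_n: int = 7

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f", f)
        if times.shape != f.shape or times.ndim != 1:
            raise InvalidParameterError("times and f must be 1-D of equal length")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise InvalidParameterError("f must be finite")
        if not 1 <= self.baseline_n <= times.size:
            raise InvalidParameterError("baseline_n out of range")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PhaseWindows:
    """Named, non-overlapping time windows (label, start, end) in minutes."""

    windows: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, start, end in self.windows:
            if not start < end:
                raise InvalidParameterError(f"window {label!r}: require start < end")
        spans = sorted((s, e) for _, s, e in self.windows)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidParameterError("windows must not overlap")


def default_baseline_n(n_prestim: int, lo: int = 5, hi: int = 7) -> int:
    """Pick the baseline length: ``hi`` when available, else what exists.

    The convention is a baseline of the first five to seven points; with
    fewer than five pre-stimulus points the baseline is rejected.
    """
    if n_prestim < lo:
        raise InvalidParameterError(
            f"need at least {lo} pre-stimulus points, got {n_prestim}"
        )
    return min(hi, n_prestim)


def delta_f_over_f(
    trace: RoiTrace,
    baseline_bounds: tuple[int, int] = (5, 7),
) -> RoiTrace:
    """Normalize a trace to its baseline: dF/F0 = (F - F0)/F0.

    F0 is the mean of the first ``trace.baseline_n`` points; by default
    ``baseline_n`` must lie in [5, 7] (the conventional baseline span),
    which ``baseline_bounds`` relaxes when needed.  The result is invariant
    to multiplying F by any positive constant, and its baseline mean is 0.
    """
    lo, hi = baseline_bounds
    if not lo <= trace.baseline_n <= hi:
        warnings.warn(
            f"baseline_n={trace.baseline_n} outside the conventional range "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
    f0 = float(trace.f[: trace.baseline_n].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline mean F0={f0} is not positive")
    return RoiTrace(
        times=trace.times,
        f=(trace.f - f0) / f0,
        channel=trace.channel,
        baseline_n=trace.baseline_n,
    )


def phase_averages(
    trace: RoiTrace,
    windows: PhaseWindows | list[tuple[str, float, float]],
) -> dict[str, float]:
    """Mean of a (normalized) trace inside each named phase window.

    Timestamps falling in the closed interval [start, end] contribute; an
    empty window raises rather than silently returning zero.
    """
    if not isinstance(windows, PhaseWindows):
        windows = PhaseWindows(windows)
    out: dict[str, float] = {}
    for label, start, end in windows.windows:
        sel = (trace.times >= start) & (trace.times <= end)
        if not sel.any():
            raise EmptyWindowError(f"window {label!r} [{start}, {end}] contains no samples")
        out[label] = float(trace.f[sel].mean())
    return out


def expansion_correct(
    sizes: np.ndarray | float,
    pre_areas: np.ndarray,
    post_areas: np.ndarray,
    convention: str = "area",
) -> tuple[np.ndarray | float, float]:
    """Rescale expansion-microscopy sizes to pre-expansion units.

    The expansion factor divides the mean nuclei area after expansion by
    that before.  Under ``convention="area"`` the factor is that area ratio
    itself (the literal determination); under ``convention="linear"`` it is
    its square root, appropriate when the corrected quantity is a length
    (e.g. a vesicle diameter).  Corrected size = measured size / factor.

    Returns (corrected sizes, factor).
    """
    pre = np.asarray(pre_areas, dtype=float)
    post = np.asarray(post_areas, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise InvalidParameterError("area sets must be non-empty")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise InvalidParameterError("areas must be positive")
    ratio = float(post.mean() / pre.mean())
    if convention == "area":
        factor = ratio
    elif convention == "linear":
        factor = float(np.sqrt(ratio))
    else:
        raise InvalidParameterError(f"unknown convention {convention!r}")
    sizes_arr = np.asarray(sizes, dtype=float)
    corrected = sizes_arr / factor
    if np.ndim(sizes) == 0:
        return float(corrected), factor
    return corrected, factor
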