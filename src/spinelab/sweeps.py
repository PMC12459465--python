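"""Uncaging-locked sweep analysis of fast reporter release.

During a structural-LTP induction protocol (30 uncaging pulses at 0.5 Hz),
fast per-pulse release of a pH-sensitive reporter rides on a slow
spine-volume signal.  To isolate it, the stimulated-spine trace is cut into
fixed-length sweeps of 16 frames (2.048 s at 0.128 s/frame), one per
uncaging interval, with the pulse falling between the second and third
frame of each sweep.  Each sweep is normalized to the mean of its own first
two frames (removing the accumulated volume/release background), selected
sweeps are averaged frame-wise, and the response is quantified as the mean
of the three frames immediately after the pulse (0.128-0.384 s latency).

Sweep numbering is 1-based in user-facing arguments, matching protocol
descriptions: with 7 baseline (no-uncaging) sweeps, uncaging pulse k falls
in sweep 7 + k, so pulses 2-18 select sweeps 9-25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError
from .timecourse import RoiTrace

__all__ = [
    "SweepMatrix",
    "PairedComparison",
    "segment_sweeps",
    "normalize_sweeps",
    "average_sweeps",
    "peak_response",
    "paired_channel_comparison",
    "plot_sweep_heatmap",
    "FRAME_INTERVAL_S",
    "FRAMES_PER_SWEEP",
    "N_BASELINE_SWEEPS",
    "DEFAULT_PULSE_RANGE",
]

#: Frame interval (s) of the 7.8 Hz acquisition, rounded so that 16 frames
#: span one 2.048-s uncaging interval exactly.
FRAME_INTERVAL_S = 0.128
FRAMES_PER_SWEEP = 16
N_BASELINE_SWEEPS = 7
#: Uncaging pulses averaged by default (1-based, inclusive).
DEFAULT_PULSE_RANGE = (2, 18)


@dataclass(frozen=True)
class SweepMatrix:
    """Sweeps x frames matrix of (optionally normalized) fluorescence.

    ``pulse_frame`` is the 1-based index of the frame after which the
    uncaging pulse falls (default 2: pulse between frames 2 and 3).
    ``valid`` flags sweeps whose per-sweep baseline was usable.
    """

    values: np.ndarray
    frame_interval: float = FRAME_INTERVAL_S
    pulse_frame: int = 2
    n_baseline_sweeps: int = N_BASELINE_SWEEPS
    normalized: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise InvalidParameterError("values must be a 2-D sweeps x frames matrix")
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(values.shape[0], dtype=bool))
        else:
            object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    @property
    def n_sweeps(self) -> int:
        return int(self.values.shape[0])

    @property
    def frames_per_sweep(self) -> int:
        return int(self.values.shape[1])

    @property
    def sweep_duration(self) -> float:
        """Sweep duration in seconds (= the uncaging period)."""
        return self.frames_per_sweep * self.frame_interval

    @property
    def frame_latencies(self) -> np.ndarray:
        """Within-sweep frame times (s) relative to the sweep start."""
        return np.arange(self.frames_per_sweep) * self.frame_interval

    def sweep_for_pulse(self, pulse: int) -> int:
        """1-based sweep index holding uncaging pulse ``pulse`` (1-based)."""
        return self.n_baseline_sweeps + pulse


def segment_sweeps(
    trace: RoiTrace | np.ndarray,
    frames_per_sweep: int = FRAMES_PER_SWEEP,
    n_baseline_sweeps: int = N_BASELINE_SWEEPS,
    frame_interval: float = FRAME_INTERVAL_S,
    pulse_frame: int = 2,
) -> SweepMatrix:
    """Cut a frame series into consecutive non-overlapping sweeps.

    A trailing partial sweep is dropped with a warning; a trace shorter
    than one sweep is an error.
    """
    values = trace.f if isinstance(trace, RoiTrace) else np.asarray(trace, dtype=float)
    if values.ndim != 1:
        raise InvalidParameterError("trace must be 1-D")
    n = values.size
    if n < frames_per_sweep:
        raise InvalidParameterError(
            f"trace of {n} frames is shorter than one sweep ({frames_per_sweep} frames)"
        )
    n_sweeps = n // frames_per_sweep
    dropped = n - n_sweeps * frames_per_sweep
    if dropped:
        warnings.warn(
            f"dropping trailing partial sweep of {dropped} frame(s)", stacklevel=2
        )
    mat = values[: n_sweeps * frames_per_sweep].reshape(n_sweeps, frames_per_sweep)
    return SweepMatrix(
        values=mat,
        frame_interval=frame_interval,
        pulse_frame=pulse_frame,
        n_baseline_sweeps=n_baseline_sweeps,
        normalized=False,
    )


def normalize_sweeps(matrix: SweepMatrix, n_baseline_frames: int = 2) -> SweepMatrix:
    """Per-sweep dF/F0 against the mean of each sweep's first frames.

    Each sweep is normalized to the average of its own first
    ``n_baseline_frames`` frames (default two), so the per-sweep baseline
    maps to 0 and the accumulated slow background cancels.  Sweeps with a
    non-positive baseline are flagged invalid (NaN rows), not dropped.
    """
    if matrix.normalized:
        raise InvalidParameterError("matrix is already normalized")
    base = matrix.values[:, :n_baseline_frames].mean(axis=1)
    valid = base > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} sweep(s) with non-positive baseline flagged invalid",
            stacklevel=2,
        )
    out = np.full_like(matrix.values, np.nan)
    out[valid] = matrix.values[valid] / base[valid, None] - 1.0
    return replace(matrix, values=out, normalized=True, valid=valid)


def _pulse_rows(matrix: SweepMatrix, pulse_range: tuple[int, int]) -> np.ndarray:
    first, last = pulse_range
    if first < 1 or first > last:
        raise InvalidParameterError(f"bad pulse range {pulse_range}")
    rows = np.arange(
        matrix.sweep_for_pulse(first) - 1, matrix.sweep_for_pulse(last)
    )  # 0-based rows
    if rows[-1] >= matrix.n_sweeps:
        bad = matrix.sweep_for_pulse(last)
        raise InvalidParameterError(
            f"pulse {last} maps to sweep {bad} but only {matrix.n_sweeps} sweeps exist"
        )
    return rows


def average_sweeps(
    matrix: SweepMatrix,
    pulse_range: tuple[int, int] = DEFAULT_PULSE_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean and SEM over the sweeps of the selected pulses.

    ``pulse_range`` is inclusive and 1-based: with 7 baseline sweeps the
    default (2, 18) averages sweeps 9-25.  Invalid (flagged) sweeps are
    excluded.  Returns (mean trace, SEM trace), each of length
    ``frames_per_sweep``.
    """
    rows = _pulse_rows(matrix, pulse_range)
    sel = matrix.values[rows]
    sel = sel[matrix.valid[rows]]
    if sel.shape[0] == 0:
        raise InvalidParameterError("no valid sweeps in the requested pulse range")
    mean = sel.mean(axis=0)
    sem = (
        sel.std(axis=0, ddof=1) / np.sqrt(sel.shape[0])
        if sel.shape[0] > 1
        else np.zeros(sel.shape[1])
    )
    return mean, sem


def peak_response(
    mean_trace: np.ndarray,
    pulse_frame: int = 2,
    n_frames: int = 3,
) -> float:
    """Uncaging-triggered response amplitude of an averaged sweep.

    Mean of the ``n_frames`` frames immediately after the pulse (frames
    ``pulse_frame+1 .. pulse_frame+n_frames``, 1-based), i.e. post-pulse
    latencies of one to three frame intervals, 0.128-0.384 s at the default
    spacing.
    """
    trace = np.asarray(mean_trace, dtype=float)
    if trace.size < pulse_frame + n_frames:
        raise InvalidParameterError(
            f"trace of {trace.size} frames too short for pulse_frame={pulse_frame} "
            f"+ {n_frames} response frames"
        )
    return float(trace[pulse_frame : pulse_frame + n_frames].mean())


def plot_sweep_heatmap(matrix: SweepMatrix, path, cmap: str = "viridis") -> None:
    """Render a sweeps x frames matrix as a trial-aligned heatmap image.

    Rows are sweeps (time runs downward), columns are within-sweep frames;
    the dashed line marks the uncaging pulse between frames ``pulse_frame``
    and ``pulse_frame + 1``.  Written as PNG (or any format the extension
    selects).
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 6.0))
    im = ax.imshow(
        matrix.values,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        extent=(0.0, matrix.sweep_duration, matrix.n_sweeps + 0.5, 0.5),
    )
    ax.axvline(matrix.pulse_frame * matrix.frame_interval, ls="--", lw=0.8, color="w")
    if matrix.n_baseline_sweeps:
        ax.axhline(matrix.n_baseline_sweeps + 0.5, ls=":", lw=0.8, color="w")
    ax.set_xlabel("time in sweep (s)")
    ax.set_ylabel("sweep")
    fig.colorbar(im, ax=ax, label=r"$\Delta F/F_0$" if matrix.normalized else "F (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class PairedComparison:
    """Two-tailed paired t-test result with degeneracy flagging."""

    statistic: float
    pvalue: float
    n: int
    mean_difference: float
    degenerate: bool = False


def paired_channel_comparison(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
) -> PairedComparison:
    """Paired t-test between per-spine peaks of two channels.

    Used to contrast reporter vs. volume responses across spines.  The
    standard two-tailed paired t statistic comes from an established
    statistics routine.  Degenerate inputs (zero-variance differences with a
    nonzero mean) are flagged rather than reported as p = 0.
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be 1-D of equal length")
    if a.size < 3:
        raise InvalidParameterError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedComparison(0.0, 1.0, a.size, 0.0, degenerate=False)
        return PairedComparison(
            np.inf if d.mean() > 0 else -np.inf,
            0.0,
            a.size,
            float(d.mean()),
            degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=a.size,
        mean_difference=float(d.mean()),
    )
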