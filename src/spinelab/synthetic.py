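"""Synthetic-data generators with ground-truth manifests.

Every analysis stage in the package has a matching generator here that
emulates the statistical structure the stage assumes, so parameter-recovery
can be verified without raw microscopy data:

* TCSPC photon histograms from the two-component IRF-convolved decay, with
  per-photon component assignment proportional to amplitude x lifetime —
  the partition under which the closed-form binding-fraction inversion is
  exact.
* FLIM image series with a prescribed binding-fraction time profile inside
  an ROI and free donor outside.
* Two-channel spine ROI movies at 7.8 Hz: a slow volume transient shared by
  both channels, plus (SEP mode only) per-pulse release transients locked
  to the uncaging schedule; a pH-stable reporter (Gamillus mode) adds none.
* Poisson event trains whose rate steps up inside a stimulation window, and
  renderable event traces for detector validation.

All generators take an explicit seed and store it in their manifest; the
manifest plus seed fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .exceptions import InvalidParameterError
from .flim import DecayParams, FlimStack, PhotonHistogram
from .timecourse import RoiTrace

__all__ = [
    "GroundTruth",
    "SpineScenario",
    "simulate_photon_histogram",
    "simulate_flim_series",
    "simulate_spine_movie",
    "simulate_event_train",
    "simulate_paired_recordings",
    "simulate_event_trace",
]

DEFAULT_PERIOD_NS = 25.0
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class GroundTruth:
    """Manifest of the true parameters behind a generated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(asdict(self), indent=2, default=_default)


# ---------------------------------------------------------------------------
# FLIM photon data
# ---------------------------------------------------------------------------


def _sample_arrivals(
    params: DecayParams, n: int, period: float, rng: np.random.Generator
) -> np.ndarray:
    """Photon arrival times under the mixture decay, reject-and-redraw.

    Each photon joins the bound component with probability
    P_AD tau_ad / (P_D tau_d + P_AD tau_ad): photon yield is proportional
    to amplitude fraction x lifetime.  Arrival = t0 + Exp(tau) + N(0, tau_g);
    draws outside [0, period) are redrawn so counts are conserved.
    """
    w_bound = params.p_ad * params.tau_ad
    w_free = params.p_d * params.tau_d
    p_bound = w_bound / (w_free + w_bound)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        bound = rng.random(m) < p_bound
        tau = np.where(bound, params.tau_ad, params.tau_d)
        t = params.t0 + rng.exponential(tau) + rng.normal(0.0, params.tau_g, size=m)
        ok = (t >= 0.0) & (t < period)
        out[todo[ok]] = t[ok]
        todo = todo[~ok]
    return out


def simulate_photon_histogram(
    params: DecayParams,
    n_photons: int,
    n_bins: int = DEFAULT_N_BINS,
    period: float = DEFAULT_PERIOD_NS,
    seed: int | np.random.Generator = 0,
) -> PhotonHistogram:
    """Simulate a TCSPC histogram of ``n_photons`` from the decay model.

    Total counts equal ``n_photons`` exactly (out-of-range arrivals are
    redrawn).  The default 25-ns period is ~9.6 donor lifetimes, so tail
    truncation is negligible.
    """
    if n_photons < 1:
        raise InvalidParameterError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    arrivals = _sample_arrivals(params, n_photons, period, rng)
    edges = np.linspace(0.0, period, n_bins + 1)
    counts, _ = np.histogram(arrivals, bins=edges)
    return PhotonHistogram(bin_edges=edges, counts=counts, period=period)


def simulate_flim_series(
    p_ad_profile: np.ndarray,
    frame_times: np.ndarray | None = None,
    shape: tuple[int, int] = (12, 12),
    roi: np.ndarray | None = None,
    photons_per_pixel: int = 200,
    background_photons: int = 50,
    tau_d: float = 2.6,
    tau_ad: float = 1.3,
    tau_g: float = 0.2,
    t0: float = 1.0,
    n_bins: int = DEFAULT_N_BINS,
    period: float = DEFAULT_PERIOD_NS,
    seed: int = 0,
) -> tuple[FlimStack, np.ndarray, GroundTruth]:
    """FLIM image series with a prescribed binding-fraction profile.

    Pixels inside ``roi`` (default: central square quarter of the frame)
    follow ``p_ad_profile[frame]``; pixels outside are free donor
    (p_ad = 0) with fewer photons.  Returns (stack, roi mask, manifest).
    """
    profile = np.asarray(p_ad_profile, dtype=float)
    n_frames = profile.size
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    rng = np.random.default_rng(seed)
    rows, cols = shape
    if roi is None:
        roi = np.zeros(shape, dtype=bool)
        roi[rows // 4 : 3 * rows // 4, cols // 4 : 3 * cols // 4] = True
    edges = np.linspace(0.0, period, n_bins + 1)
    frames = np.zeros((n_frames, rows, cols, n_bins), dtype=np.int32)
    donor = DecayParams(f0=1.0, p_ad=0.0, tau_d=tau_d, tau_ad=tau_ad, tau_g=tau_g, t0=t0)
    for k in range(n_frames):
        in_params = DecayParams(
            f0=1.0, p_ad=float(profile[k]), tau_d=tau_d, tau_ad=tau_ad, tau_g=tau_g, t0=t0
        )
        for r in range(rows):
            for c in range(cols):
                p = in_params if roi[r, c] else donor
                n = photons_per_pixel if roi[r, c] else background_photons
                if n == 0:
                    continue
                arr = _sample_arrivals(p, n, period, rng)
                frames[k, r, c], _ = np.histogram(arr, bins=edges)
    stack = FlimStack(
        frames=frames, frame_times=np.asarray(frame_times, float),
        bin_edges=edges, period=period,
    )
    truth = GroundTruth(
        scenario="flim_series",
        seed=int(seed) if isinstance(seed, int) else -1,
        params=dict(
            p_ad_profile=profile, tau_d=tau_d, tau_ad=tau_ad, tau_g=tau_g, t0=t0,
            photons_per_pixel=photons_per_pixel, background_photons=background_photons,
        ),
    )
    return stack, roi, truth


# ---------------------------------------------------------------------------
# two-channel spine movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineScenario:
    """Configuration of a simulated uncaging experiment on one spine.

    The default schedule mirrors the standard induction protocol: 7
    baseline sweeps of 16 frames at 0.128 s/frame followed by 30 uncaging
    pulses at one per 2.048-s sweep, each pulse mid-gap between the second
    and third frame of its sweep.  ``reporter_mode`` selects whether
    per-pulse release transients are visible ("SEP") or not ("Gamillus",
    pH-stable).  Noise is a shot-noise-like multiplicative Gaussian whose
    variance scales with the signal.
    """

    frame_rate: float = 7.8  # Hz, nominal
    frame_interval: float = 0.128  # s; 16 frames = 2.048 s
    frames_per_sweep: int = 16
    n_baseline_sweeps: int = 7
    n_pulses: int = 30
    reporter_mode: str = "SEP"
    # volume transient (shared by both channels), fractions of baseline
    volume_peak: float = 1.0
    volume_sustained: float = 0.4
    volume_rise_tau: float = 20.0  # s
    volume_decay_tau: float = 60.0  # s
    # per-pulse release transient (reporter channel, SEP mode only)
    release_amplitude: float = 0.15  # dF/F0 units
    release_decay_tau: float = 1.0  # s
    release_probability: float = 0.5
    # noise
    noise_sd: float = 0.04  # fractional SD at baseline
    baseline_f: float = 1000.0  # a.u.

    def __post_init__(self) -> None:
        if self.reporter_mode not in ("SEP", "Gamillus"):
            raise InvalidParameterError(
                f"reporter_mode must be 'SEP' or 'Gamillus', got {self.reporter_mode!r}"
            )
        if not 0.0 <= self.release_probability <= 1.0:
            raise InvalidParameterError("release_probability must be in [0, 1]")

    @property
    def sweep_duration(self) -> float:
        return self.frames_per_sweep * self.frame_interval

    @property
    def n_frames(self) -> int:
        return (self.n_baseline_sweeps + self.n_pulses) * self.frames_per_sweep

    @property
    def uncaging_onset(self) -> float:
        """Time (s) of the first uncaging sweep's start."""
        return self.n_baseline_sweeps * self.sweep_duration

    def pulse_time(self, pulse: int) -> float:
        """Time (s) of uncaging pulse ``pulse`` (1-based), mid-gap between
        the second and third frame of its sweep."""
        sweep_start = (self.n_baseline_sweeps + pulse - 1) * self.sweep_duration
        return sweep_start + 1.5 * self.frame_interval


def _volume_transient(t: np.ndarray, sc: SpineScenario) -> np.ndarray:
    """Fractional volume change: fast saturating rise, decay to a plateau."""
    u = t - sc.uncaging_onset
    rise = 1.0 - np.exp(-np.maximum(u, 0.0) / sc.volume_rise_tau)
    frac = sc.volume_sustained / sc.volume_peak
    decay = frac + (1.0 - frac) * np.exp(-np.maximum(u, 0.0) / sc.volume_decay_tau)
    return np.where(u >= 0.0, sc.volume_peak * rise * decay, 0.0)


def simulate_spine_movie(
    scenario: SpineScenario,
    n_spines: int = 13,
    seed: int = 0,
) -> tuple[list[dict[str, RoiTrace]], GroundTruth]:
    """Two-channel ROI traces for ``n_spines`` stimulated spines.

    Each spine yields a ``volume`` channel (cytosolic marker: baseline x
    (1 + volume transient) x noise) and a ``reporter`` channel that shares
    the volume signal and, in SEP mode, adds an instantaneous-step /
    exponential-decay transient after each successful uncaging pulse.  The
    manifest records every release event (spine, pulse, time, amplitude).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(scenario.n_frames) * scenario.frame_interval
    spines: list[dict[str, RoiTrace]] = []
    events: list[dict] = []
    for s in range(n_spines):
        vol = _volume_transient(t, scenario)
        release = np.zeros_like(t)
        if scenario.reporter_mode == "SEP":
            for k in range(1, scenario.n_pulses + 1):
                if rng.random() < scenario.release_probability:
                    tp = scenario.pulse_time(k)
                    amp = scenario.release_amplitude
                    lag = t - tp
                    release += np.where(
                        lag >= 0.0, amp * np.exp(-lag / scenario.release_decay_tau), 0.0
                    )
                    events.append(dict(spine=s, pulse=k, time=tp, amplitude=amp))
        signals = {
            "volume": scenario.baseline_f * (1.0 + vol),
            "reporter": scenario.baseline_f * (1.0 + vol + release),
        }
        traces: dict[str, RoiTrace] = {}
        for channel, sig in signals.items():
            # shot-noise proxy: variance proportional to the signal level
            sd = scenario.noise_sd * np.sqrt(sig * scenario.baseline_f)
            noisy = sig + rng.normal(0.0, 1.0, size=sig.size) * sd
            traces[channel] = RoiTrace(
                times=t, f=np.maximum(noisy, 1e-6), channel=channel,
                baseline_n=min(7, scenario.n_baseline_sweeps * scenario.frames_per_sweep),
            )
        spines.append(traces)
    truth = GroundTruth(
        scenario=f"spine_movie_{scenario.reporter_mode}",
        seed=int(seed),
        params=dict(
            n_spines=n_spines,
            scenario={k: v for k, v in asdict(scenario).items()},
            release_events=events,
            pulse_times=[scenario.pulse_time(k) for k in range(1, scenario.n_pulses + 1)],
        ),
    )
    return spines, truth


# ---------------------------------------------------------------------------
# TIRF event trains and traces
# ---------------------------------------------------------------------------


def simulate_event_train(
    basal_rate: float,
    stim_rate: float,
    recording_window: tuple[float, float] = (0.0, 120.0),
    stim_window: tuple[float, float] | None = (4.0, 64.0),
    seed: int | np.random.Generator = 0,
) -> tuple["EventTrain", GroundTruth]:  # noqa: F821
    """Inhomogeneous Poisson release-event train.

    Rate is ``basal_rate`` outside the stimulation window and ``stim_rate``
    inside it (default: a 120-s stimulated movie whose 60-s stimulation
    span starts 4 s in).  Pass ``stim_window=None`` for a homogeneous basal
    recording.
    """
    from .events import EventTrain  # local import to avoid a cycle

    if basal_rate < 0 or stim_rate < 0:
        raise InvalidParameterError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = recording_window
    segments: list[tuple[float, float, float]] = []
    if stim_window is None:
        segments.append((lo, hi, basal_rate))
    else:
        s, e = stim_window
        if not (lo <= s < e <= hi):
            raise InvalidParameterError("stim_window must lie inside recording_window")
        if s > lo:
            segments.append((lo, s, basal_rate))
        segments.append((s, e, stim_rate))
        if hi > e:
            segments.append((e, hi, basal_rate))
    times = []
    for a, b, rate in segments:
        n = rng.poisson(rate * (b - a))
        times.append(np.sort(rng.uniform(a, b, size=n)))
    event_times = np.concatenate(times) if times else np.array([])
    train = EventTrain(
        event_times=np.sort(event_times),
        recording_window=recording_window,
        stim_window=stim_window,
    )
    truth = GroundTruth(
        scenario="event_train",
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        params=dict(
            basal_rate=basal_rate, stim_rate=stim_rate,
            recording_window=list(recording_window),
            stim_window=list(stim_window) if stim_window else None,
        ),
    )
    return train, truth


def simulate_paired_recordings(
    n_recordings: int,
    basal_rate: float = 0.01,
    stim_rate: float = 0.05,
    basal_duration: float = 60.0,
    stim_recording: tuple[float, float] = (0.0, 120.0),
    stim_window: tuple[float, float] = (4.0, 64.0),
    seed: int = 0,
) -> list[tuple["EventTrain", "EventTrain"]]:
    """Paired basal/stimulated recordings, the before-after TIRF design.

    Each recording contributes a 60-s basal movie (homogeneous at
    ``basal_rate``) and a stimulated movie whose rate steps to
    ``stim_rate`` inside the stimulation window.  Default rates are sparse
    dense-core-vesicle release rates (one event per 100 s basal, one per
    20 s stimulated).
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_recordings):
        basal, _ = simulate_event_train(
            basal_rate, basal_rate, recording_window=(0.0, basal_duration),
            stim_window=None, seed=rng,
        )
        stim, _ = simulate_event_train(
            basal_rate, stim_rate, recording_window=stim_recording,
            stim_window=stim_window, seed=rng,
        )
        pairs.append((basal, stim))
    return pairs


def simulate_event_trace(
    event_times: np.ndarray,
    duration: float,
    frame_rate: float = 20.0,
    amplitude: float = 1.0,
    rise_time: float = 0.05,
    decay_tau: float = 0.5,
    baseline: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> RoiTrace:
    """Render an event train as a noisy fluorescence trace.

    Each event is a saturating-exponential rise (time scale ``rise_time``)
    followed by an exponential decay with constant ``decay_tau``, on a flat
    baseline with additive Gaussian noise.  Used to validate the reference
    peak detector against ground truth.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    f = np.full_like(t, baseline)
    for te in np.asarray(event_times, dtype=float):
        lag = t - te
        pulse = np.where(
            lag >= 0.0,
            amplitude * (1.0 - np.exp(-np.maximum(lag, 0) / rise_time))
            * np.exp(-np.maximum(lag, 0) / decay_tau),
            0.0,
        )
        f += pulse
    f += rng.normal(0.0, noise_sd, size=f.size)
    return RoiTrace(times=t, f=f, channel="SEP")
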