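"""FLIM-FRET decay model, fitting, lifetime maps and binding-fraction estimation.

Time-correlated single-photon counting (TCSPC) of a FRET donor gives a
fluorescence decay that is a mixture of a free-donor component (lifetime
``tau_d``) and a bound-donor component quenched by FRET (``tau_ad < tau_d``),
each convolved with a Gaussian instrument pulse response of width ``tau_g``:

    F(t) = F0 * [P_D * H(t; t0, tau_d, tau_g) + P_AD * H(t; t0, tau_ad, tau_g)]

where ``P_AD`` is the fraction of donors bound to acceptor (``P_D = 1 -
P_AD``) and each component is the exponentially-modified Gaussian

    H(t) = 1/2 * exp(tau_g^2/(2 tau^2) - (t-t0)/tau)
               * erfc((tau_g^2 - tau (t-t0)) / (sqrt(2) tau tau_g)).

The per-photon mean arrival time <t> relates to the mean lifetime by the
offset ``t0`` fitted on the pooled whole-image decay, <tau> = <t> - t0, and
the binding fraction follows in closed form:

    P_AD = tau_d (tau_d - <tau>) / [(tau_d - tau_ad)(tau_d + tau_ad - <tau>)]

This inversion is exact when the photon yield of each component is
proportional to (amplitude fraction x lifetime), which is how photon counts
partition between two exponentials of equal radiative rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import erfc, erfcx

from .exceptions import (
    InsufficientPhotonsError,
    InvalidParameterError,
    UndefinedMeanError,
)

#: Free-eGFP donor lifetime (ns) used as the fixed tau_d in all fits.
EGFP_LIFETIME_NS = 2.6

#: Baseline binding fraction above which a cell is excluded from analysis.
QC_BASELINE_THRESHOLD = 0.45

__all__ = [
    "DecayParams",
    "PhotonHistogram",
    "FlimStack",
    "LifetimeMap",
    "BindingTrace",
    "FitResult",
    "decay_component",
    "model_curve",
    "fit_decay",
    "mean_arrival_time",
    "binding_fraction_from_mean",
    "mixture_mean_lifetime",
    "lifetime_map",
    "roi_binding_timecourse",
    "qc_filter_cells",
    "EGFP_LIFETIME_NS",
    "QC_BASELINE_THRESHOLD",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the two-component IRF-convolved decay model.

    Attributes
    ----------
    f0 : float
        Peak amplitude before convolution (photon counts / bin).
    p_ad : float
        Bound-donor (FRET) fraction in [0, 1]; the free fraction is
        ``p_d = 1 - p_ad``.
    tau_d : float
        Free-donor lifetime (ns).
    tau_ad : float
        Bound-donor lifetime (ns); must satisfy ``0 < tau_ad < tau_d``.
    tau_g : float
        Gaussian pulse-response (IRF) width (ns).
    t0 : float
        Arrival-time offset of the laser pulse (ns).
    """

    f0: float
    p_ad: float
    tau_d: float = EGFP_LIFETIME_NS
    tau_ad: float = 1.3
    tau_g: float = 0.2
    t0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ad <= 1.0:
            raise InvalidParameterError(f"p_ad must be in [0, 1], got {self.p_ad}")
        if not 0.0 < self.tau_ad < self.tau_d:
            raise InvalidParameterError(
                f"require 0 < tau_ad < tau_d, got tau_ad={self.tau_ad}, tau_d={self.tau_d}"
            )
        if self.tau_g <= 0:
            raise InvalidParameterError(f"tau_g must be positive, got {self.tau_g}")
        if self.f0 <= 0:
            raise InvalidParameterError(f"f0 must be positive, got {self.f0}")

    @property
    def p_d(self) -> float:
        """Free-donor fraction."""
        return 1.0 - self.p_ad


@dataclass(frozen=True)
class PhotonHistogram:
    """Binned photon arrival counts for one ROI or one pooled image.

    ``bin_edges`` is a uniform grid of length ``len(counts) + 1`` in ns;
    ``period`` is the laser repetition interval (ns) bounding the last edge.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    period: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or edges.ndim != 1 or len(edges) != len(counts) + 1:
            raise InvalidParameterError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if edges[-1] > self.period + 1e-9:
            raise InvalidParameterError("last bin edge exceeds the laser period")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FlimStack:
    """A time series of per-pixel TCSPC frames.

    ``frames`` has shape (n_frames, rows, cols, n_bins); ``frame_times`` are
    acquisition times in seconds, strictly increasing.  Bin configuration is
    shared across frames.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    bin_edges: np.ndarray
    period: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.frame_times, dtype=float)
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "bin_edges", edges)
        if frames.ndim != 4:
            raise InvalidParameterError("frames must be (n_frames, rows, cols, n_bins)")
        if frames.shape[0] != times.size:
            raise InvalidParameterError("frame_times length must match frame count")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise InvalidParameterError("frame_times must be strictly increasing")
        if frames.shape[-1] != edges.size - 1:
            raise InvalidParameterError("last frame axis must match bin count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def pooled_histogram(self) -> PhotonHistogram:
        """Histogram pooled over all pixels and frames (whole-image decay)."""
        counts = self.frames.sum(axis=(0, 1, 2))
        return PhotonHistogram(self.bin_edges, counts, self.period)

    def frame_histogram(self, index: int, mask: np.ndarray | None = None) -> PhotonHistogram:
        """Histogram of one frame pooled over ``mask`` (all pixels if None)."""
        frame = self.frames[index]
        if mask is not None:
            counts = frame[np.asarray(mask, bool)].sum(axis=0)
        else:
            counts = frame.sum(axis=(0, 1))
        return PhotonHistogram(self.bin_edges, counts, self.period)


@dataclass(frozen=True)
class LifetimeMap:
    """Per-pixel mean-lifetime image with a validity mask."""

    mean_tau: np.ndarray  # ns; NaN where masked
    photons: np.ndarray
    mask: np.ndarray  # True where the pixel is valid
    t0: float

    def __post_init__(self) -> None:
        if not (self.mean_tau.shape == self.photons.shape == self.mask.shape):
            raise InvalidParameterError("mean_tau, photons and mask shapes must agree")


@dataclass(frozen=True)
class BindingTrace:
    """Binding-fraction time series with baseline normalization.

    ``delta_p_ad`` is ``p_ad`` minus the mean binding fraction over the
    baseline (pre-stimulus) window, i.e. P_AD - P_AD0.
    """

    times: np.ndarray
    p_ad: np.ndarray
    baseline_window: tuple[int, int]
    delta_p_ad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        p_ad = np.asarray(self.p_ad, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p_ad", p_ad)
        lo, hi = self.baseline_window
        if not 0 <= lo < hi <= p_ad.size:
            raise InvalidParameterError("baseline_window out of range")
        if self.delta_p_ad is None:
            object.__setattr__(self, "delta_p_ad", p_ad - self.baseline)

    @property
    def baseline(self) -> float:
        """Mean baseline binding fraction P_AD0 (NaN-aware)."""
        lo, hi = self.baseline_window
        window = self.p_ad[lo:hi]
        if np.all(np.isnan(window)):
            return np.nan
        return float(np.nanmean(window))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a decay fit: parameters plus diagnostics."""

    params: DecayParams
    log_likelihood: float
    converged: bool
    n_photons: int
    message: str = ""


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def decay_component(
    t: np.ndarray | float, t0: float, tau: float, tau_g: float
) -> np.ndarray | float:
    """Single exponential decay convolved with a Gaussian pulse response.

    Evaluates H(t) = 1/2 exp(tau_g^2/(2 tau^2) - (t-t0)/tau)
    * erfc((tau_g^2 - tau (t-t0)) / (sqrt(2) tau tau_g)) in an
    overflow-safe form: for non-negative erfc argument ``z`` the identity
    ``erfc(z) = erfcx(z) exp(-z^2)`` collapses the exponent to
    ``-(t-t0)^2 / (2 tau_g^2)``; for negative ``z`` the direct prefactor
    exponent is itself negative, so either branch stays finite.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    if tau_g <= 0:
        raise InvalidParameterError(f"tau_g must be positive, got {tau_g}")
    u = np.asarray(t, dtype=float) - t0
    z = (tau_g * tau_g - tau * u) / (np.sqrt(2.0) * tau * tau_g)
    pos = z >= 0
    out = np.empty_like(u)
    # z >= 0 (early times): 1/2 erfcx(z) exp(-u^2 / 2 tau_g^2)
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-(u[pos] ** 2) / (2.0 * tau_g * tau_g))
    # z < 0 (decay tail): direct form; exponent < 0 there
    neg = ~pos
    out[neg] = (
        0.5
        * np.exp(tau_g * tau_g / (2.0 * tau * tau) - u[neg] / tau)
        * erfc(z[neg])
    )
    if np.ndim(t) == 0:
        return float(out)
    return out


def model_curve(params: DecayParams, t_grid: np.ndarray) -> np.ndarray:
    """Two-component decay F(t) on a time grid (ns).

    F(t) = f0 [ p_d H(t; tau_d) + p_ad H(t; tau_ad) ], both components
    sharing t0 and the IRF width tau_g.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    h_d = decay_component(t_grid, params.t0, params.tau_d, params.tau_g)
    h_ad = decay_component(t_grid, params.t0, params.tau_ad, params.tau_g)
    return params.f0 * (params.p_d * h_d + params.p_ad * h_ad)


def mixture_mean_lifetime(p_ad: float, tau_d: float, tau_ad: float) -> float:
    """Photon-weighted mean lifetime of the two-component mixture.

    With photon yield proportional to amplitude x lifetime,
    <tau> = (P_D tau_d^2 + P_AD tau_ad^2) / (P_D tau_d + P_AD tau_ad).
    """
    p_d = 1.0 - p_ad
    return (p_d * tau_d**2 + p_ad * tau_ad**2) / (p_d * tau_d + p_ad * tau_ad)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def mean_arrival_time(hist: PhotonHistogram) -> float:
    """Count-weighted mean photon arrival time <t> (ns) of a histogram."""
    total = hist.counts.sum()
    if total <= 0:
        raise UndefinedMeanError("cannot take the mean arrival time of an empty histogram")
    return float((hist.counts * hist.bin_centers).sum() / total)


def binding_fraction_from_mean(
    mean_tau: float,
    tau_d: float = EGFP_LIFETIME_NS,
    tau_ad: float = 1.3,
    clip: bool = False,
) -> float:
    """Closed-form binding fraction from the mean donor lifetime.

    P_AD = tau_d (tau_d - <tau>) / [(tau_d - tau_ad)(tau_d + tau_ad - <tau>)].
    Exactly inverts :func:`mixture_mean_lifetime`.  Noise can push the
    estimate outside [0, 1]; such values are returned as-is with a warning
    unless ``clip`` is set.
    """
    if not tau_ad < tau_d:
        raise InvalidParameterError(f"require tau_ad < tau_d, got {tau_ad} >= {tau_d}")
    denom = (tau_d - tau_ad) * (tau_d + tau_ad - mean_tau)
    if abs(denom) < 1e-9 * tau_d * tau_d:
        raise ZeroDivisionError(
            f"degenerate denominator: tau_d + tau_ad == mean_tau == {mean_tau}"
        )
    p = tau_d * (tau_d - mean_tau) / denom
    if clip:
        return float(np.clip(p, 0.0, 1.0))
    if not 0.0 <= p <= 1.0:
        warnings.warn(
            f"binding fraction {p:.4f} outside [0, 1]; pass clip=True to clamp",
            stacklevel=2,
        )
    return float(p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _bin_model(
    theta: np.ndarray,
    tau_d: float,
    edges: np.ndarray,
    bin_integration: bool,
) -> np.ndarray:
    """Unit-amplitude model shape per bin for fit parameters theta."""
    p_ad, tau_ad, t0, tau_g = theta
    params = dict(t0=t0, tau_g=tau_g)
    if bin_integration:
        # Simpson on each bin: (f(a) + 4 f(m) + f(b)) / 6
        a, b = edges[:-1], edges[1:]
        m = 0.5 * (a + b)
        def shape(pts: np.ndarray) -> np.ndarray:
            h_d = decay_component(pts, params["t0"], tau_d, params["tau_g"])
            h_ad = decay_component(pts, params["t0"], tau_ad, params["tau_g"])
            return (1.0 - p_ad) * h_d + p_ad * h_ad
        return (shape(a) + 4.0 * shape(m) + shape(b)) / 6.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    h_d = decay_component(centers, t0, tau_d, tau_g)
    h_ad = decay_component(centers, t0, tau_ad, tau_g)
    return (1.0 - p_ad) * h_d + p_ad * h_ad


def _initial_t0(hist: PhotonHistogram) -> float:
    """Rising-edge half-maximum of the histogram, a robust t0 seed."""
    c = hist.counts.astype(float)
    peak = c.max()
    if peak <= 0:
        return float(hist.bin_centers[0])
    idx = int(np.argmax(c >= 0.5 * peak))
    return float(hist.bin_centers[idx])


def fit_decay(
    hist: PhotonHistogram,
    tau_d_fixed: float = EGFP_LIFETIME_NS,
    init: DecayParams | None = None,
    min_photons: int = 10_000,
    objective: str = "poisson",
    bin_integration: bool = False,
) -> FitResult:
    """Fit the two-component decay to a histogram with tau_d held fixed.

    Maximizes the Poisson likelihood of the binned counts (TCSPC counts are
    Poisson) over (p_ad, tau_ad, t0, tau_g); the amplitude is profiled out
    analytically since, at fixed shape, the Poisson-optimal scale is
    total_counts / sum(shape).  ``objective="wls"`` switches to weighted
    least squares with variance = max(counts, 1) as a diagnostic fallback.

    Parameters
    ----------
    hist : PhotonHistogram
        Measured decay (pooled image or ROI).
    tau_d_fixed : float
        Free-donor lifetime (ns); never altered by the optimizer.  Default
        2.6 ns, the lifetime of free eGFP.
    init : DecayParams, optional
        Starting point; a deterministic default is derived from the data.
    min_photons : int
        Photon floor below which fitting is refused.
    """
    if tau_d_fixed <= 0:
        raise InvalidParameterError("tau_d_fixed must be positive")
    if objective not in ("poisson", "wls"):
        raise InvalidParameterError(f"unknown objective {objective!r}")
    total = hist.total
    if total < min_photons:
        raise InsufficientPhotonsError(
            f"histogram has {total} photons, below the floor of {min_photons}"
        )

    counts = hist.counts.astype(float)
    edges = hist.bin_edges
    if init is None:
        theta0 = np.array([0.2, tau_d_fixed / 2.0, _initial_t0(hist), 0.15])
    else:
        theta0 = np.array([init.p_ad, init.tau_ad, init.t0, init.tau_g])

    tau_ad_hi = tau_d_fixed - 1e-3
    bounds = [
        (0.0, 1.0),
        (0.1, tau_ad_hi),
        (float(edges[0]), float(edges[-1]) / 2.0),
        (0.02, 1.0),
    ]
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    if objective == "poisson":

        def nll(theta: np.ndarray) -> float:
            s = _bin_model(theta, tau_d_fixed, edges, bin_integration)
            s = np.maximum(s, 1e-300)
            ssum = s.sum()
            # with the amplitude profiled out, sum(mu) = total is constant
            return float(total * np.log(ssum) - (counts * np.log(s)).sum())

        objective_fn = nll
    else:
        w = 1.0 / np.maximum(counts, 1.0)

        def wls(theta: np.ndarray) -> float:
            s = _bin_model(theta, tau_d_fixed, edges, bin_integration)
            ssum = s.sum()
            if ssum <= 0:
                return np.inf
            mu = total * s / ssum
            return float((w * (counts - mu) ** 2).sum())

        objective_fn = wls

    res = minimize(objective_fn, theta0, method="L-BFGS-B", bounds=bounds)
    p_ad, tau_ad, t0, tau_g = res.x
    shape = _bin_model(res.x, tau_d_fixed, edges, bin_integration)
    scale = total / shape.sum()
    mu = np.maximum(scale * shape, 1e-300)
    loglik = float((counts * np.log(mu) - mu).sum())

    # f0 is the pre-convolution peak amplitude per bin of width dt
    params = DecayParams(
        f0=float(scale),
        p_ad=float(p_ad),
        tau_d=float(tau_d_fixed),
        tau_ad=float(tau_ad),
        tau_g=float(tau_g),
        t0=float(t0),
    )
    if not res.success:
        warnings.warn(f"decay fit did not converge: {res.message}", stacklevel=2)
    return FitResult(
        params=params,
        log_likelihood=loglik,
        converged=bool(res.success),
        n_photons=total,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def lifetime_map(
    frame: np.ndarray,
    bin_edges: np.ndarray,
    t0: float,
    min_photons: int = 10,
) -> LifetimeMap:
    """Per-pixel mean-lifetime image from one TCSPC frame.

    ``frame`` has shape (rows, cols, n_bins).  Each pixel's mean arrival
    time is converted to a mean lifetime by subtracting the image-level
    offset ``t0`` (obtained from a pooled whole-image fit).  Pixels with
    fewer than ``min_photons`` photons are masked.
    """
    frame = np.asarray(frame)
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    photons = frame.sum(axis=-1)
    mask = photons >= max(min_photons, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = (frame * centers).sum(axis=-1) / photons
    mean_tau = np.where(mask, mean_t - t0, np.nan)
    return LifetimeMap(mean_tau=mean_tau, photons=photons, mask=mask, t0=t0)


def roi_binding_timecourse(
    stack: FlimStack,
    roi: np.ndarray,
    params: DecayParams,
    baseline_window: tuple[int, int],
    min_photons: int = 100,
    clip: bool = False,
) -> BindingTrace:
    """Binding-fraction time course of an ROI (spine or dendrite).

    Per frame, photons inside ``roi`` are pooled into one histogram whose
    mean arrival time, offset by ``params.t0``, yields the mean lifetime and
    thence the binding fraction.  Frames below the photon floor are masked
    (NaN).  The trace is baseline-normalized as P_AD - P_AD0 with P_AD0 the
    mean over ``baseline_window``.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise InvalidParameterError("roi must contain at least one pixel")
    p_ad = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        hist = stack.frame_histogram(i, mask=roi)
        if hist.total < min_photons:
            continue
        mean_tau = mean_arrival_time(hist) - params.t0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_ad[i] = binding_fraction_from_mean(
                mean_tau, params.tau_d, params.tau_ad, clip=clip
            )
    return BindingTrace(times=stack.frame_times, p_ad=p_ad, baseline_window=baseline_window)


def qc_filter_cells(
    cells: Mapping[str, float] | Sequence[float] | np.ndarray,
    threshold: float = QC_BASELINE_THRESHOLD,
) -> dict[str, float] | np.ndarray:
    """Keep cells whose average baseline binding fraction is <= threshold.

    Mirrors the inclusion rule that cells start the experiment with an
    initial binding fraction not higher than 45%.  Accepts a mapping
    (cell id -> baseline P_AD) or an array; returns the retained subset in
    the same form (for arrays, the retained values).
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError(f"threshold must be in (0, 1], got {threshold}")
    if isinstance(cells, Mapping):
        return {k: v for k, v in cells.items() if v <= threshold}
    arr = np.asarray(cells, dtype=float)
    return arr[arr <= threshold]
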