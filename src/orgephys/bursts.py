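"""Network-burst detection and burst-LFP spectral parametrization.

Bursts are detected on the binned (0.1 s), normalized and smoothed multi-unit
activity (MUA) vector: peaks above mean + 2 SD of the normalized vector mark
bursts, and each burst is extended to the nearest crossings of a lower
threshold (the mean) to define onset and offset. Because the vector is
normalized, the rule is scale-free: rescaling the MUA changes nothing.

Burst-period LFP spectra are estimated with Welch's method on the 1-kHz
signal, and each spectrum is decomposed into an aperiodic 1/f component plus
Gaussian oscillatory peaks; peak center frequencies are pooled across bursts
and channel groups to find the most likely oscillation frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d

from .spiketable import SpikeTable

__all__ = [
    "BurstEvent",
    "detect_bursts",
    "burst_rate",
    "welch_psd",
    "SpectralModel",
    "parametrize_spectrum",
    "most_likely_peak",
]


@dataclass(frozen=True)
class BurstEvent:
    onset: float
    offset: float
    peak_time: float

    def __post_init__(self):
        if not self.onset <= self.peak_time <= self.offset:
            raise ValueError("burst peak must lie within [onset, offset]")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def mua_vector(spikes: SpikeTable, duration: float, bin_s: float = 0.1) -> np.ndarray:
    """Population spike counts in ``bin_s`` bins over [0, duration)."""
    n_bins = int(np.ceil(duration / bin_s))
    counts, _ = np.histogram(spikes.t, bins=n_bins, range=(0.0, n_bins * bin_s))
    return counts.astype(float)


def detect_bursts(
    spikes: SpikeTable,
    duration: float,
    bin_s: float = 0.1,
    smooth_sd_s: float = 0.3,
    min_duration_s: float = 0.5,
) -> list[BurstEvent]:
    """Detect network bursts on the normalized, smoothed MUA vector.

    The MUA is binned at ``bin_s``, Gaussian-smoothed (SD ``smooth_sd_s``) and
    normalized to the maximum of the smoothed vector. Peaks of the smoothed
    vector above its mean + 2 SD are burst peaks; onset and offset are the
    nearest crossings of the mean level by the *unsmoothed* normalized vector
    (reading the edges from the raw vector avoids widening every event by
    about twice the smoothing SD). Bursts separated by less than one bin are
    merged and bursts shorter than ``min_duration_s`` discarded.
    """
    if duration <= 10 * bin_s:
        raise ValueError("recording must span more than 10 MUA bins")
    mua = mua_vector(spikes, duration, bin_s)
    if mua.max() == 0:
        return []
    smoothed = gaussian_filter1d(mua, sigma=smooth_sd_s / bin_s, mode="nearest")
    norm = smoothed / smoothed.max()
    raw_norm = mua / smoothed.max()
    # detection statistics come from the unsmoothed normalized vector; the
    # smoothed vector only stabilizes peak finding. Using the raw SD keeps the
    # threshold honest (smoothing shrinks the SD and would admit noise peaks).
    thr_hi = raw_norm.mean() + 2.0 * raw_norm.std()
    thr_lo = raw_norm.mean()  # Gaussian smoothing preserves the mean
    peaks, _ = signal.find_peaks(norm, height=thr_hi)
    if norm[0] > thr_hi and (norm.size < 2 or norm[0] >= norm[1]):
        peaks = np.concatenate([[0], peaks])
    if norm[-1] > thr_hi and (norm.size < 2 or norm[-1] > norm[-2]):
        peaks = np.concatenate([peaks, [norm.size - 1]])
    below = raw_norm < thr_lo
    events: list[tuple[int, int, int]] = []
    for p in peaks:
        left = np.flatnonzero(below[: p + 1])
        i0 = int(left[-1]) + 1 if left.size else 0
        right = np.flatnonzero(below[p:])
        i1 = p + int(right[0]) - 1 if right.size else norm.size - 1
        events.append((i0, i1, int(p)))
    if not events:
        return []
    # merge overlapping / near-adjacent excursions (multiple peaks in one burst)
    events.sort()
    merged = [events[0]]
    for i0, i1, p in events[1:]:
        m0, m1, mp = merged[-1]
        if i0 <= m1 + 1:  # gap < 1 bin
            p_best = p if norm[p] > norm[mp] else mp
            merged[-1] = (m0, max(m1, i1), p_best)
        else:
            merged.append((i0, i1, p))
    out = []
    for i0, i1, p in merged:
        onset, offset = i0 * bin_s, min((i1 + 1) * bin_s, duration)
        if offset - onset < min_duration_s:
            continue
        peak_t = min(max((p + 0.5) * bin_s, onset), offset)
        out.append(BurstEvent(onset=onset, offset=offset, peak_time=peak_t))
    return out


def burst_rate(events, duration: float) -> float:
    """Bursts per second (Hz)."""
    return len(events) / float(duration)


# ---------------------------------------------------------------------------
# burst-period spectra


def welch_psd(
    lfp: np.ndarray,
    fs: float,
    windows,
    fs_target: float = 1000.0,
    segment_s: float = 1.0,
) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Welch power spectra of burst-period LFP per channel group.

    ``lfp`` is (n_groups, n_samples) at ``fs``; it is resampled to
    ``fs_target`` (1 kHz) first. For each burst window at least one Welch
    segment (Hann, ``segment_s`` long, 50% overlap) must fit, otherwise the
    window is skipped with a warning.

    Returns ``(freqs, psds)`` where ``psds[group][burst]`` is the power
    spectrum of that group during that burst.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if fs != fs_target:
        up, down = int(round(fs_target)), int(round(fs))
        lfp = signal.resample_poly(lfp, up, down, axis=1)
        fs = fs_target
    nperseg = int(round(segment_s * fs))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    psds: list[list[np.ndarray]] = [[] for _ in range(lfp.shape[0])]
    for onset, offset in np.asarray(windows, dtype=float).reshape(-1, 2):
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        i0, i1 = max(i0, 0), min(i1, lfp.shape[1])
        if i1 - i0 < nperseg:
            warnings.warn(
                f"burst window [{onset:.2f}, {offset:.2f}) s shorter than one "
                f"Welch segment ({segment_s} s); skipped"
            )
            continue
        f, p = signal.welch(
            lfp[:, i0:i1], fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
        )
        for g in range(lfp.shape[0]):
            psds[g].append(p[g])
    return freqs, psds


@dataclass
class SpectralModel:
    """Aperiodic + Gaussian-peaks decomposition of a log-power spectrum.

    ``log10 P(f) = offset - exponent * log10 f + sum_k h_k exp(-(f-c_k)^2/(2 w_k^2))``

    Peaks are (center_hz, power, bandwidth_hz) with power in log10-power units
    above the aperiodic component.
    """

    offset: float
    exponent: float
    peaks: list = field(default_factory=list)
    f_range: tuple = (2.0, 100.0)
    fit_ok: bool = True

    def aperiodic(self, f: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(f)

    def model(self, f: np.ndarray) -> np.ndarray:
        out = self.aperiodic(f)
        for c, h, w in self.peaks:
            out = out + h * np.exp(-0.5 * ((f - c) / w) ** 2)
        return out


def _gauss(f, c, h, w):
    return h * np.exp(-0.5 * ((f - c) / w) ** 2)


def _fit_aperiodic(logf, logp):
    # robust two-pass straight-line fit: refit on the points least affected by peaks
    b, a = np.polyfit(logf, logp, 1)
    resid = logp - (b * logf + a)
    mask = resid <= np.quantile(resid, 0.75)
    if mask.sum() >= 2:
        b, a = np.polyfit(logf[mask], logp[mask], 1)
    return a, -b  # offset, exponent


def parametrize_spectrum(
    freqs: np.ndarray,
    psd: np.ndarray,
    f_range: tuple = (2.0, 100.0),
    min_peak_power: float = 0.3,
    max_peaks: int = 6,
    bw_bounds: tuple = (1.0, 12.0),
) -> SpectralModel:
    """Fit an aperiodic 1/f component plus Gaussian oscillatory peaks.

    Works on log10 power over ``f_range`` (2-100 Hz): an initial robust
    aperiodic fit is subtracted, then Gaussians are extracted iteratively from
    the residual (largest first, at most ``max_peaks``, bandwidth bounded to
    ``bw_bounds``); candidates below ``min_peak_power`` (log10-power units
    above the aperiodic component) are rejected. The aperiodic component is
    refit on the peak-subtracted spectrum. On fit failure the aperiodic-only
    model is returned with a warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    f, p = freqs[sel], psd[sel]
    if f.size < 4:
        raise ValueError("need at least 4 frequency samples in the fit range")
    if np.any(p <= 0):
        raise ValueError("psd must be strictly positive on the fit range")
    logf, logp = np.log10(f), np.log10(p)
    offset, exponent = _fit_aperiodic(logf, logp)
    try:
        resid = logp - (offset - exponent * logf)
        peaks = []
        for _ in range(max_peaks):
            i = int(np.argmax(resid))
            h0 = resid[i]
            if h0 < min_peak_power:
                break
            # half-height width guess
            above = resid >= h0 / 2
            j0 = i
            while j0 > 0 and above[j0 - 1]:
                j0 -= 1
            j1 = i
            while j1 < f.size - 1 and above[j1 + 1]:
                j1 += 1
            w0 = np.clip((f[j1] - f[j0]) / 2.355 or 1.0, *bw_bounds)
            try:
                (c, h, w), _ = optimize.curve_fit(
                    _gauss,
                    f,
                    resid,
                    p0=[f[i], h0, w0],
                    bounds=([f[0], 0.0, bw_bounds[0]], [f[-1], np.inf, bw_bounds[1]]),
                    maxfev=2000,
                )
            except RuntimeError:
                break
            if h < min_peak_power:
                break
            peaks.append((float(c), float(h), float(w)))
            resid = resid - _gauss(f, c, h, w)
        if peaks:
            # refit the aperiodic component with the peaks removed
            flat = logp - sum(_gauss(f, *pk) for pk in peaks)
            b, a = np.polyfit(logf, flat, 1)
            offset, exponent = a, -b
        return SpectralModel(
            offset=float(offset),
            exponent=float(exponent),
            peaks=peaks,
            f_range=tuple(f_range),
        )
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"spectral peak fit failed ({exc}); returning aperiodic-only model")
        return SpectralModel(
            offset=float(offset), exponent=float(exponent), peaks=[], f_range=tuple(f_range),
            fit_ok=False,
        )


def most_likely_peak(models, f_range: tuple = (2.0, 100.0), kde_bw: float = 1.0) -> float | None:
    """Most likely oscillatory peak frequency pooled over spectral models.

    Pools the center frequency of every fitted peak across bursts and channel
    groups and returns the mode of a Gaussian kernel density (bandwidth
    ``kde_bw`` Hz) evaluated on a 0.05-Hz grid. None when no peaks were found.
    """
    centers = np.array([c for m in models for (c, h, w) in m.peaks], dtype=float)
    if centers.size == 0:
        return None
    if centers.size == 1:
        return float(centers[0])
    grid = np.arange(f_range[0], f_range[1] + 1e-9, 0.05)
    dens = np.exp(-0.5 * ((grid[:, None] - centers[None, :]) / kde_bw) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])
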