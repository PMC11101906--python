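"""LFP spectral analysis, waveform featurization/clustering, opto-tagging.

LFP traces are zero-phase low-pass filtered (8-pole Butterworth, 250 Hz)
and their power spectral density estimated with Welch's method; relative
band power is the ratio of integrated PSD within a band of interest
(default gamma, 30-80 Hz) to total power over (0, lowpass].

Extracellular waveforms are summarized by trough-to-peak duration,
trough-to-peak amplitude ratio, and post-peak repolarization slope, then
clustered with k-means (k=3 by default).

Opto-tag classification: a unit is tagged if it is responsive to light
pulses both before and after a glutamatergic blocker (responsiveness via
the same cumulative-latency shuffle-null machinery as the timing module),
with median light-evoked latency < 10 ms and low jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .io_model import SpikeTrain, StimulusEvent
from .timing import _cumulative_curve, first_spike_latencies, shuffle_band
from .synthetic import stream

GAMMA_BAND = (30.0, 80.0)


@dataclass
class LFPResult:
    freqs_hz: np.ndarray
    psd: np.ndarray           # (channels, freqs)
    psd_mean: np.ndarray      # channel-averaged
    relative_band_power: float
    band: tuple


@dataclass
class WaveformFeatures:
    unit_id: str
    trough_to_peak_ms: Optional[float]
    trough_to_peak_ratio: Optional[float]
    repolarization_slope: Optional[float]  # uV/ms over 0.5 ms after peak
    cluster_id: Optional[int] = None
    valid: bool = True
    reason: str = ""


@dataclass
class OptoTagResult:
    unit_id: str
    responsive_pre: Optional[bool]
    responsive_post: Optional[bool]
    median_latency_ms: Optional[float]
    jitter_ms: Optional[float]
    tagged: Optional[bool]
    reason: str = ""


def lfp_spectrum(traces: np.ndarray, fs_hz: float, lowpass_hz: float = 250.0,
                 filter_order: int = 8, band: tuple = GAMMA_BAND) -> LFPResult:
    """Filtered Welch PSD and relative band power of an LFP recording.

    ``traces`` is (channels, samples) or (samples,).  The filter is applied
    forward-backward (zero phase); Welch segments are the power of two
    nearest 2 s with 50% overlap; relative band power integrates the
    channel-averaged PSD by trapezoid over ``band`` against (0, lowpass].
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] / fs_hz < 10.0:
        raise ValueError("LFP trace must be at least 10 s long")
    if fs_hz <= 2 * lowpass_hz:
        raise ValueError("fs_hz must exceed twice the low-pass corner")
    lo, hi = band
    if not (0.0 < lo < hi <= lowpass_hz):
        raise ValueError(f"band {band} outside (0, {lowpass_hz}]")

    sos = sps.butter(filter_order, lowpass_hz, btype="low", fs=fs_hz,
                     output="sos")
    filt = sps.sosfiltfilt(sos, traces, axis=1)
    nperseg = int(2 ** round(np.log2(2.0 * fs_hz)))
    nperseg = min(nperseg, traces.shape[1])
    freqs, psd = sps.welch(filt, fs=fs_hz, nperseg=nperseg,
                           noverlap=nperseg // 2, axis=1)
    psd_mean = psd.mean(axis=0)

    in_band = (freqs >= lo) & (freqs <= hi)
    in_total = (freqs > 0) & (freqs <= lowpass_hz)
    num = np.trapezoid(psd_mean[in_band], freqs[in_band])
    den = np.trapezoid(psd_mean[in_total], freqs[in_total])
    rel = float(num / den) if den > 0 else np.nan
    return LFPResult(freqs, psd, psd_mean, rel, band)


def waveform_features(waveform: np.ndarray, fs_hz: float,
                      unit_id: str = "", slope_window_ms: float = 0.5
                      ) -> WaveformFeatures:
    """Trough-to-peak duration/ratio and post-peak repolarization slope.

    Expects a biphasic waveform with a global trough followed by a peak.
    """
    w = np.asarray(waveform, dtype=float)
    i_tr = int(np.argmin(w))
    post = w[i_tr + 1:]
    if post.size == 0 or post.max() <= 0:
        return WaveformFeatures(unit_id, None, None, None, valid=False,
                                reason="no post-trough peak")
    i_pk = i_tr + 1 + int(np.argmax(post))
    duration_ms = (i_pk - i_tr) / fs_hz * 1e3
    ratio = abs(w[i_tr]) / abs(w[i_pk])
    n_slope = max(int(round(slope_window_ms / 1e3 * fs_hz)), 2)
    seg = w[i_pk:i_pk + n_slope]
    t_ms = np.arange(seg.size) / fs_hz * 1e3
    slope = float(np.polyfit(t_ms, seg, 1)[0]) if seg.size >= 2 else np.nan
    return WaveformFeatures(unit_id, float(duration_ms), float(ratio), slope)


def cluster_waveforms(features: Sequence[WaveformFeatures], k: int = 3,
                      n_restarts: int = 20, seed: int = None):
    """K-means over standardized (duration, ratio, slope) features.

    Assigns ``cluster_id`` in place on the valid features and returns
    ``(features, centroids, degenerate)``; ``degenerate`` flags an
    all-identical feature matrix (single effective cluster).
    """
    if seed is None:
        raise ValueError("an explicit seed is required for k-means restarts")
    valid = [f for f in features if f.valid]
    if len(valid) < k:
        raise ValueError(f"{len(valid)} units with valid features; need >= {k}")
    X = np.array([[f.trough_to_peak_ms, f.trough_to_peak_ratio,
                   f.repolarization_slope] for f in valid])
    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        for f in valid:
            f.cluster_id = 0
        return list(features), np.tile(X[0], (1, 1)), True
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
    labels = km.fit_predict(Xs)
    for f, lab in zip(valid, labels):
        f.cluster_id = int(lab)
    return list(features), km.cluster_centers_, False


def _light_onsets(pulses: Sequence[StimulusEvent]) -> np.ndarray:
    return np.array([p.onset_s for p in pulses])


def _block_response(train: SpikeTrain, pulses, response_window_s: float,
                    n_shuffles: int, alpha: float,
                    rng: np.random.Generator):
    """Responsiveness of one light block via the cumulative shuffle null.

    The null redraws each pulse's local spikes uniformly over a window ten
    times the response window (pulses are sparse; there is no 1.5 s
    pre-pulse baseline convention as for indentation).
    """
    onsets = _light_onsets(pulses)
    bin_s = 1e-3
    n_bins = int(round(response_window_s / bin_s))
    edges = bin_s * np.arange(n_bins + 1)
    lat = first_spike_latencies(train, onsets, response_window_s)
    empirical = _cumulative_curve(lat, edges)

    span = 10.0 * response_window_s
    t = train.spike_times
    counts = np.array([
        int(np.searchsorted(t, on + response_window_s)
            - np.searchsorted(t, on - (span - response_window_s)))
        for on in onsets
    ])
    null = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        shuf = np.full(onsets.size, np.nan)
        for kk in range(onsets.size):
            if counts[kk] == 0:
                continue
            u = rng.random(counts[kk]) * span - (span - response_window_s)
            u = u[(u > 0) & (u <= response_window_s)]
            if u.size:
                shuf[kk] = u.min()
        null[s] = _cumulative_curve(shuf, edges)
    upper = shuffle_band(null, alpha)
    responsive = bool(np.any(empirical > upper))
    return responsive, lat


def classify_optotag(train: SpikeTrain, pulses_pre, pulses_post,
                     response_window_ms: float = 10.0,
                     jitter_max_ms: float = 3.0, n_shuffles: int = 100,
                     alpha: float = 0.05, seed: int = None,
                     min_pulses: int = 25) -> OptoTagResult:
    """Opto-tag a unit from light responses before and after the blocker.

    Tagged requires: responsive in both blocks, median light-evoked
    first-spike latency < 10 ms, and jitter <= ``jitter_max_ms``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for the shuffle null")
    if not pulses_post:
        return OptoTagResult(train.unit_id, None, None, None, None, None,
                             reason="missing post-blocker block")
    for name, pulses in (("pre", pulses_pre), ("post", pulses_post)):
        if len(pulses) < min_pulses:
            raise ValueError(
                f"{name}-blocker block has {len(pulses)} pulses; "
                f"need >= {min_pulses}")
    rw = response_window_ms / 1e3
    rng = stream(seed, "optotag", train.unit_id)
    resp_pre, lat_pre = _block_response(train, pulses_pre, rw, n_shuffles,
                                        alpha, rng)
    resp_post, lat_post = _block_response(train, pulses_post, rw, n_shuffles,
                                          alpha, rng)
    lat = np.concatenate([lat_pre, lat_post])
    lat = lat[~np.isnan(lat)]
    med = float(np.median(lat) * 1e3) if lat.size else None
    jit = float(np.std(lat, ddof=1) * 1e3) if lat.size > 1 else 0.0
    tagged = bool(resp_pre and resp_post and med is not None
                  and med < 10.0 and jit <= jitter_max_ms)
    return OptoTagResult(train.unit_id, resp_pre, resp_post, med, jit, tagged)
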