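"""Response tuning: PSTHs, windowed evoked rates, bootstrap thresholds,
and brush response maxima.

Indentation steps are subdivided into three response windows — ON
(0–50 ms after onset), OFF (0–50 ms after offset), SUSTAINED (0–200 ms
before offset) — with baseline firing measured over the 1.5 s preceding
each step.  A unit's force threshold is the smallest force whose
trial-mean rate in any window exceeds a bootstrap upper confidence bound
of baseline firing; units with no threshold carry ``None`` (excluded as
"baseline firing only").

Threshold-bootstrap calibration: each bootstrap replicate measures
baseline firing in randomly placed windows *length-matched* to the tested
response window, so the null replicate has the same sampling variance as
the test statistic; the default multiplicity correction is Bonferroni
across all tested force-window combinations (``correction="none"``
disables it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._binning import count_in_windows
from .io_model import SpikeTrain, StimulusEvent
from .synthetic import stream

ON_MS = 50.0
OFF_MS = 50.0
SUSTAINED_MS = 200.0
BASELINE_S = 1.5


@dataclass
class PSTH:
    """Trial-averaged peristimulus time histogram (time relative to onset)."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    baseline_hz: float
    variant: str  # raw | baseline_subtracted | zscored
    n_trials: int


@dataclass
class TuningCurve:
    """Per-force windowed evoked rates with SEM and the detected threshold."""

    unit_id: str
    forces_mN: np.ndarray
    on_hz: np.ndarray
    off_hz: np.ndarray
    sustained_hz: np.ndarray
    on_sem: np.ndarray
    off_sem: np.ndarray
    sustained_sem: np.ndarray
    baseline_hz: float
    threshold_mN: Optional[float]


@dataclass
class BrushResponse:
    """Per-minute maxima of the smoothed brush-evoked rate and their mean."""

    unit_id: str
    minute_max_hz: np.ndarray
    mean_max_hz: float
    included: bool
    reason: str = ""


def _check_trials(events: Sequence[StimulusEvent]) -> None:
    if not events:
        raise ValueError("need at least one trial")
    if any(e.kind != "indentation" for e in events):
        raise ValueError("trials must be indentation events")


def trial_windows(events, which: str):
    """(t0, t1) response or baseline windows for each trial."""
    out = []
    for e in events:
        if which == "on":
            out.append((e.onset_s, e.onset_s + ON_MS / 1e3))
        elif which == "off":
            out.append((e.offset_s, e.offset_s + OFF_MS / 1e3))
        elif which == "sustained":
            out.append((e.offset_s - SUSTAINED_MS / 1e3, e.offset_s))
        elif which == "baseline":
            out.append((e.onset_s - BASELINE_S, e.onset_s))
        else:
            raise ValueError(f"unknown window {which!r}")
    return out


def baseline_rates(train: SpikeTrain, events) -> np.ndarray:
    """Per-trial baseline firing rate over the 1.5 s before each onset."""
    return np.array([
        count_in_windows(train.spike_times, [w]) / BASELINE_S
        for w in trial_windows(events, "baseline")
    ])


def compute_psth(train: SpikeTrain, events, bin_ms: float = 10.0,
                 variant: str = "raw", post_s: float = 0.3) -> PSTH:
    """Trial-averaged PSTH over [-1.5 s, step + post_s] around onset."""
    _check_trials(events)
    if variant not in ("raw", "baseline_subtracted", "zscored"):
        raise ValueError(f"unknown variant {variant!r}")
    step = events[0].duration_s
    bin_s = bin_ms / 1e3
    lo, hi = -BASELINE_S, step + post_s
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for e in events:
        rel = train.spike_times - e.onset_s
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rate = counts / (len(events) * bin_s)

    base_bins = rate[edges[:-1] < -1e-9]
    base_mean = float(base_bins.mean())
    base_sd = float(base_bins.std(ddof=1)) if base_bins.size > 1 else 0.0
    if variant == "baseline_subtracted":
        rate = rate - base_mean
    elif variant == "zscored":
        if base_sd == 0:
            return PSTH(edges, np.full(n_bins, np.nan), base_mean, variant,
                        len(events))
        rate = (rate - base_mean) / base_sd
    return PSTH(edges, rate, base_mean, variant, len(events))


def window_rates(train: SpikeTrain, events, subtract_baseline: bool = False):
    """Per-trial (on, off, sustained) rates in Hz plus trial means.

    Returns a dict with per-trial arrays ``on``, ``off``, ``sustained``,
    ``baseline`` and scalar means ``on_hz``, ``off_hz``, ``sustained_hz``.
    """
    _check_trials(events)
    step = events[0].duration_s
    if step < 0.25:
        raise ValueError(
            f"step duration {step} s < 0.25 s: ON and SUSTAINED windows "
            "would overlap the onset transient")
    per = {}
    for which, width in (("on", ON_MS / 1e3), ("off", OFF_MS / 1e3),
                         ("sustained", SUSTAINED_MS / 1e3)):
        per[which] = np.array([
            count_in_windows(train.spike_times, [w]) / width
            for w in trial_windows(events, which)
        ])
    per["baseline"] = baseline_rates(train, events)
    if subtract_baseline:
        for which in ("on", "off", "sustained"):
            per[which] = per[which] - per["baseline"]
    per["on_hz"] = float(per["on"].mean())
    per["off_hz"] = float(per["off"].mean())
    per["sustained_hz"] = float(per["sustained"].mean())
    return per


def _bootstrap_baseline_bound(train: SpikeTrain, events, window_s: float,
                              n_boot: int, q: float,
                              rng: np.random.Generator,
                              n_eff: Optional[int] = None) -> float:
    """Upper bound of baseline firing measured in length-matched windows.

    Each replicate resamples ``n_eff`` trials with replacement (the number
    of trials behind each tested per-force statistic, so the replicate mean
    has the test statistic's sampling variance), measures the baseline rate
    of each in one randomly placed ``window_s``-long sub-window of its
    1.5 s baseline, and takes the mean; the bound is the ``q`` quantile of
    the replicate means.
    """
    n_tr = len(events)
    n_eff = n_tr if n_eff is None else n_eff
    onsets = np.array([e.onset_s for e in events])
    t = train.spike_times
    idx = rng.integers(0, n_tr, size=(n_boot, n_eff))
    u = rng.random((n_boot, n_eff)) * (BASELINE_S - window_s)
    starts = onsets[idx] - BASELINE_S + u
    lo = np.searchsorted(t, starts)
    hi = np.searchsorted(t, starts + window_s)
    rates = (hi - lo) / window_s
    return float(np.quantile(rates.mean(axis=1), q))


def detect_threshold(train: SpikeTrain, events, n_boot: int = 1000,
                     alpha: float = 0.05, seed: int = None,
                     correction: str = "bonferroni",
                     min_trials: int = 10) -> Optional[float]:
    """Smallest force whose ON/OFF/SUSTAINED trial-mean rate exceeds the
    bootstrap upper confidence bound of baseline firing; None if no window
    at any force responds (unit excluded as baseline-only).

    ``correction`` controls the family-wise level across the tested
    force-window combinations: ``"bonferroni"`` (default) or ``"none"``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for the bootstrap")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    _check_trials(events)
    forces = sorted({e.force_mN for e in events})
    by_force = {f: [e for e in events if e.force_mN == f] for f in forces}
    for f, evs in by_force.items():
        if len(evs) < min_trials:
            raise ValueError(
                f"force {f} mN has {len(evs)} trials; need >= {min_trials}")
    n_tests = len(forces) * 3
    a = alpha / n_tests if correction == "bonferroni" else alpha
    q = 1.0 - a / 2.0
    rng = stream(seed, "threshold", train.unit_id)

    widths = {"on": ON_MS / 1e3, "off": OFF_MS / 1e3,
              "sustained": SUSTAINED_MS / 1e3}
    n_eff = min(len(evs) for evs in by_force.values())
    bounds = {
        w: _bootstrap_baseline_bound(train, events, widths[w], n_boot, q, rng,
                                     n_eff=n_eff)
        for w in widths
    }
    for f in forces:
        per = window_rates(train, by_force[f])
        for w in widths:
            if per[f"{w}_hz"] > bounds[w]:
                return float(f)
    return None


def tuning_curve(train: SpikeTrain, events, n_boot: int = 1000,
                 alpha: float = 0.05, seed: int = None) -> TuningCurve:
    """Per-force windowed rates with SEM plus the detected threshold."""
    _check_trials(events)
    forces = sorted({e.force_mN for e in events})
    stats = {k: [] for k in ("on", "off", "sustained",
                             "on_sem", "off_sem", "sustained_sem")}
    for f in forces:
        per = window_rates(train, [e for e in events if e.force_mN == f])
        for w in ("on", "off", "sustained"):
            x = per[w]
            stats[w].append(x.mean())
            stats[f"{w}_sem"].append(x.std(ddof=1) / np.sqrt(x.size)
                                     if x.size > 1 else np.nan)
    thr = detect_threshold(train, events, n_boot=n_boot, alpha=alpha,
                           seed=seed)
    return TuningCurve(
        train.unit_id, np.asarray(forces, dtype=float),
        np.asarray(stats["on"]), np.asarray(stats["off"]),
        np.asarray(stats["sustained"]), np.asarray(stats["on_sem"]),
        np.asarray(stats["off_sem"]), np.asarray(stats["sustained_sem"]),
        float(baseline_rates(train, events).mean()), thr)


def brush_max_rates(train: SpikeTrain, brush_event: StimulusEvent,
                    smooth_bin_ms: float = 100.0,
                    baseline_events=None, n_boot: int = 1000,
                    alpha: float = 0.05, seed: int = None) -> BrushResponse:
    """Per-minute maxima of the smoothed brush-evoked rate, averaged.

    The rate trace is binned at ``smooth_bin_ms``; for each whole minute of
    the brush epoch the maximum binned rate is taken and the per-minute
    maxima are averaged.  When ``baseline_events`` (indentation trials with
    pre-stimulus baselines) are given, the unit is only included if its mean
    brush-epoch rate exceeds the same bootstrap baseline bound used for
    threshold detection (length-matched to ``smooth_bin_ms`` windows is not
    needed here: the brush mean is a long-duration statistic, so the bound
    uses full 1.5 s baselines).
    """
    dur = brush_event.duration_s
    if dur < 60.0:
        raise ValueError("brush epoch must be at least one minute")
    if baseline_events is not None:
        if seed is None:
            raise ValueError("seed required for the inclusion bootstrap")
        rates = baseline_rates(train, baseline_events)
        rng = stream(seed, "brush", train.unit_id)
        boots = rng.choice(rates, size=(n_boot, rates.size),
                           replace=True).mean(axis=1)
        bound = float(np.quantile(boots, 1 - alpha / 2))
        brush_rate = count_in_windows(
            train.spike_times, [(brush_event.onset_s, brush_event.offset_s)]
        ) / dur
        if brush_rate <= bound:
            return BrushResponse(train.unit_id, np.zeros(0), np.nan, False,
                                 "no response above baseline")
    bin_s = smooth_bin_ms / 1e3
    n_min = int(dur // 60)
    maxima = []
    for m in range(n_min):
        t0 = brush_event.onset_s + 60.0 * m
        n_bins = int(round(60.0 / bin_s))
        edges = t0 + bin_s * np.arange(n_bins + 1)
        counts, _ = np.histogram(train.spike_times, bins=edges)
        maxima.append(counts.max() / bin_s)
    maxima = np.asarray(maxima, dtype=float)
    return BrushResponse(train.unit_id, maxima, float(maxima.mean()), True)
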