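"""Firing-correlation analyses.

* **Population coupling** — each unit's spike-triggered population rate
  (stPR) at lag 0, own spikes excluded, computed on 1 ms-binned counts over
  an analysis epoch.  To compare across recordings it is normalized by
  subtracting the median stPR of a shuffle null in which the trigger
  unit's spike times are redrawn uniformly over the epoch while the rest
  of the population is held fixed.  The normalized value ("normalized
  population firing rate", Hz) is high for units whose spikes ride
  population-wide events ("choristers") and near zero for independent
  units ("soloists").
* **Pairwise synchrony** — Pearson correlation of two units' 1 ms binned
  counts at lag 0, plus the full cross-correlogram over +/-50 ms.
* **Noise correlations** — Pearson correlation across trials of spike
  counts in matched spontaneous windows (per-trial 1.5 s baselines).
* **Signal correlations** — Pearson correlation of trial-averaged
  response PSTHs (50 ms bins) concatenated across stimuli of one class.

Epochs are unions of windows; binned counts are concatenated across
windows and lagged statistics never straddle a window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._binning import (
    Windows,
    baseline_windows,
    bin_session,
    bin_windows,
    brush_windows,
    epoch_duration,
    indentation_windows,
)
from .io_model import DEFAULT_DEPTH_BOUNDARY_UM, Session
from .synthetic import stream

MIN_UNITS_FOR_COUPLING = 5
MIN_SPIKES = 10


@dataclass
class CouplingResult:
    """Normalized population coupling for one unit."""

    unit_id: str
    stpr_lag0_hz: Optional[float]
    shuffle_median_hz: Optional[float]
    coupling_hz: Optional[float]
    bin_ms: float
    stratum: str = "all"
    epoch: str = "evoked"
    n_spikes: int = 0
    reason: str = ""


@dataclass
class PairCorrelation:
    """Pairwise correlation measures for one unit pair."""

    unit_a: str
    unit_b: str
    sync_r: Optional[float] = None
    noise_r: Optional[float] = None
    signal_r: Optional[float] = None
    lags_ms: Optional[np.ndarray] = None
    ccg: Optional[np.ndarray] = None
    epoch: str = "full"
    reason: str = ""


def resolve_epoch(session: Session, epoch: str | Windows) -> Windows:
    """Named epoch -> window list.  Accepts an explicit window list too.

    Named epochs: ``evoked`` (union of ON+OFF+SUSTAINED windows across
    indentation trials), ``full_step``, ``onset``, ``offset``,
    ``sustained``, ``spontaneous`` (per-trial baselines), ``brush``,
    ``all`` (whole recording).
    """
    if not isinstance(epoch, str):
        return list(epoch)
    if epoch == "evoked":
        return indentation_windows(session)
    if epoch == "full_step":
        return indentation_windows(session, parts=("full",))
    if epoch in ("onset", "on"):
        return indentation_windows(session, parts=("on",))
    if epoch in ("offset", "off"):
        return indentation_windows(session, parts=("off",))
    if epoch == "sustained":
        return indentation_windows(session, parts=("sustained",))
    if epoch == "spontaneous":
        return baseline_windows(session)
    if epoch == "brush":
        return brush_windows(session)
    if epoch == "all":
        t_stop = min(tr.t_stop for tr, _ in session.units)
        return [(0.0, t_stop)]
    raise ValueError(f"unknown epoch {epoch!r}")


def population_rate(session: Session, bin_ms: float = 1.0,
                    epoch: str | Windows = "all") -> np.ndarray:
    """Summed per-bin spike counts across all units over the epoch."""
    windows = resolve_epoch(session, epoch)
    if not windows:
        raise ValueError("empty epoch")
    if session.n_units < 1:
        raise ValueError("need at least one unit")
    counts, _ = bin_session(session, windows, bin_ms / 1e3)
    return counts.sum(axis=0)


def _coupling_from_counts(counts: np.ndarray, bin_s: float,
                          n_shuffles: int, rng: np.random.Generator):
    """Per-unit normalized coupling from a counts matrix.

    Observed stPR(0) for unit i = sum_b n_i[b] * pop_excl_i[b] / N_i,
    converted to Hz by / bin_s; the null redraws unit i's N_i spikes
    uniformly over the epoch bins with the rest of the population fixed.
    """
    n_units, n_bins = counts.shape
    pop = counts.sum(axis=0)
    out = []
    for i in range(n_units):
        n_i = counts[i]
        N = int(n_i.sum())
        if N < MIN_SPIKES:
            out.append((None, None, None, N,
                        f"only {N} spikes in epoch (min {MIN_SPIKES})"))
            continue
        pop_excl = pop - n_i
        observed = float(n_i @ pop_excl) / N / bin_s
        draws = rng.integers(0, n_bins, size=(n_shuffles, N))
        null = pop_excl[draws].mean(axis=1) / bin_s
        med = float(np.median(null))
        out.append((observed, med, observed - med, N, ""))
    return out


def population_coupling(session: Session, bin_ms: float = 1.0,
                        epoch: str | Windows = "evoked",
                        n_shuffles: int = 100, stratum: str = "all",
                        boundary_um: float = DEFAULT_DEPTH_BOUNDARY_UM,
                        seed: int = None) -> list:
    """Normalized population coupling for every unit; list of CouplingResult.

    With ``stratum`` in {"superficial", "deep"} both the trigger units and
    the population are restricted to units on that side of ``boundary_um``
    (superficial = depth < boundary).
    """
    if seed is None:
        raise ValueError("an explicit seed is required for the shuffle null")
    sub = session
    if stratum != "all":
        keep = [m.unit_id for _, m in session.units
                if m.stratum(boundary_um) == stratum]
        if len(keep) < MIN_UNITS_FOR_COUPLING:
            raise ValueError(
                f"stratum {stratum!r} has {len(keep)} units; "
                f"coupling needs >= {MIN_UNITS_FOR_COUPLING}")
        sub = session.subset(keep)
    if sub.n_units < MIN_UNITS_FOR_COUPLING:
        raise ValueError(
            f"coupling needs >= {MIN_UNITS_FOR_COUPLING} simultaneous units")
    windows = resolve_epoch(sub, epoch)
    if not windows:
        raise ValueError("empty epoch")
    bin_s = bin_ms / 1e3
    counts, _ = bin_session(sub, windows, bin_s)
    rng = stream(seed, "coupling", bin_ms, stratum)
    rows = _coupling_from_counts(counts, bin_s, n_shuffles, rng)
    label = epoch if isinstance(epoch, str) else "custom"
    return [
        CouplingResult(m.unit_id, obs, med, cpl, bin_ms, stratum, label,
                       n, reason)
        for (_, m), (obs, med, cpl, n, reason) in zip(sub.units, rows)
    ]


def coupling_bin_sweep(session: Session, bins_ms: Sequence[float] = (1, 3, 10),
                       epoch: str | Windows = "evoked",
                       n_shuffles: int = 100, stratum: str = "all",
                       boundary_um: float = DEFAULT_DEPTH_BOUNDARY_UM,
                       seed: int = None) -> dict:
    """Population coupling at several bin sizes; {bin_ms: [CouplingResult]}."""
    return {
        b: population_coupling(session, bin_ms=b, epoch=epoch,
                               n_shuffles=n_shuffles, stratum=stratum,
                               boundary_um=boundary_um, seed=seed)
        for b in bins_ms
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    # symmetric arithmetic: _pearson(x, y) == _pearson(y, x) bit for bit
    if x.size < 2:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    den2 = float(xc @ xc) * float(yc @ yc)
    if den2 == 0.0:
        return None
    return float(xc @ yc) / np.sqrt(den2)


def _lagged_pairs(x: np.ndarray, y: np.ndarray, slices, lag: int):
    """Aligned (x[t], y[t+lag]) samples, never straddling a window."""
    xs, ys = [], []
    for start, n in slices:
        if n <= abs(lag):
            continue
        a, b = x[start:start + n], y[start:start + n]
        if lag >= 0:
            xs.append(a[:n - lag])
            ys.append(b[lag:])
        else:
            xs.append(a[-lag:])
            ys.append(b[:n + lag])
    if not xs:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(xs), np.concatenate(ys)


def cross_correlogram(x: np.ndarray, y: np.ndarray, slices,
                      max_lag_bins: int):
    """Pearson correlation of binned counts at each lag in +/-max_lag."""
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    ccg = np.full(lags.size, np.nan)
    for k, lag in enumerate(lags):
        a, b = _lagged_pairs(x, y, slices, int(lag))
        r = _pearson(a, b)
        ccg[k] = np.nan if r is None else r
    return lags, ccg


def pairwise_synchrony(session: Session, bin_ms: float = 1.0,
                       epoch: str | Windows = "full_step",
                       max_lag_ms: float = 50.0,
                       with_ccg: bool = True) -> list:
    """Lag-0 synchrony (and cross-correlogram) for every unit pair."""
    windows = resolve_epoch(session, epoch)
    if not windows:
        raise ValueError("empty epoch")
    bin_s = bin_ms / 1e3
    counts, slices = bin_session(session, windows, bin_s)
    max_lag_bins = int(round(max_lag_ms / bin_ms))
    label = epoch if isinstance(epoch, str) else "custom"
    out = []
    ids = session.unit_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            x, y = counts[i], counts[j]
            if x.sum() < MIN_SPIKES or y.sum() < MIN_SPIKES:
                out.append(PairCorrelation(
                    ids[i], ids[j], epoch=label,
                    reason=f"<{MIN_SPIKES} spikes in epoch"))
                continue
            r = _pearson(x.astype(float), y.astype(float))
            pc = PairCorrelation(ids[i], ids[j], sync_r=r, epoch=label,
                                 reason="" if r is not None
                                 else "zero-variance counts")
            if with_ccg and r is not None:
                lags, ccg = cross_correlogram(x.astype(float),
                                              y.astype(float), slices,
                                              max_lag_bins)
                pc.lags_ms = lags * bin_ms
                pc.ccg = ccg
            out.append(pc)
    return out


def noise_correlations(session: Session,
                       windows: Optional[Windows] = None,
                       min_windows: int = 20) -> list:
    """Trial-by-trial spike-count correlations over spontaneous windows.

    Defaults to the per-trial 1.5 s pre-stimulus baselines.
    """
    if windows is None:
        windows = baseline_windows(session)
    if len(windows) < min_windows:
        raise ValueError(
            f"{len(windows)} windows; noise correlations need "
            f">= {min_windows}")
    counts = np.array([
        [int(np.searchsorted(tr.spike_times, t1)
             - np.searchsorted(tr.spike_times, t0)) for t0, t1 in windows]
        for tr, _ in session.units
    ], dtype=float)
    ids = session.unit_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = _pearson(counts[i], counts[j])
            out.append(PairCorrelation(
                ids[i], ids[j], noise_r=r, epoch="spontaneous",
                reason="" if r is not None else "zero-variance counts"))
    return out


def mean_response_vector(train, events_by_stim: dict,
                         psth_bin_ms: float = 50.0) -> np.ndarray:
    """Concatenated trial-mean response vector across stimuli of one class.

    For indentation, ``events_by_stim`` maps force -> trials and each
    stimulus contributes the binned mean rate over [onset, offset].
    """
    parts = []
    bin_s = psth_bin_ms / 1e3
    for _, evs in sorted(events_by_stim.items()):
        dur = evs[0].duration_s
        n_bins = int(np.floor(dur / bin_s + 1e-9))
        acc = np.zeros(n_bins)
        for e in evs:
            c, _ = bin_windows(train.spike_times,
                               [(e.onset_s, e.onset_s + n_bins * bin_s)],
                               bin_s)
            acc += c
        parts.append(acc / (len(evs) * bin_s))
    return np.concatenate(parts)


def signal_correlation_from_psths(psth_a: np.ndarray,
                                  psth_b: np.ndarray) -> Optional[float]:
    """Pearson correlation of two concatenated mean-response vectors."""
    a, b = np.asarray(psth_a, float), np.asarray(psth_b, float)
    if a.size < 4:
        raise ValueError("need at least 4 concatenated PSTH bins")
    return _pearson(a, b)


def signal_correlations(session: Session, stimulus: str = "indentation",
                        psth_bin_ms: float = 50.0) -> list:
    """Tuning-similarity (signal) correlations for every unit pair."""
    if stimulus == "indentation":
        events_by_stim = {
            f: session.events_of("indentation", force_mN=f)
            for f in session.forces()
        }
    elif stimulus == "brush":
        events_by_stim = {0: session.events_of("brush")}
    else:
        raise ValueError(f"unknown stimulus class {stimulus!r}")
    if not events_by_stim or not any(events_by_stim.values()):
        raise ValueError(f"no {stimulus} events in session")
    vecs = [mean_response_vector(tr, events_by_stim, psth_bin_ms)
            for tr, _ in session.units]
    if vecs[0].size < 4:
        raise ValueError("fewer than 4 concatenated PSTH bins")
    ids = session.unit_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = _pearson(vecs[i], vecs[j])
            out.append(PairCorrelation(
                ids[i], ids[j], signal_r=r, epoch=stimulus,
                reason="" if r is not None else "zero-variance response"))
    return out


def stratify(session: Session,
             boundary_um: float = DEFAULT_DEPTH_BOUNDARY_UM) -> dict:
    """Unit ids per depth stratum; superficial = depth in [0, boundary)."""
    out = {"superficial": [], "deep": []}
    for _, m in session.units:
        out[m.stratum(boundary_um)].append(m.unit_id)
    return out


def analytic_shared_gain_noise_r(cv: float, mu_i_hz: float, mu_j_hz: float,
                                 window_s: float) -> float:
    """Expected pairwise noise correlation under a shared lognormal gain.

    With counts over windows of length T and per-unit mean rates mu,
    rho_ij ~= cv^2 mu_i mu_j T^2 / sqrt[(mu_i T + cv^2 mu_i^2 T^2)
    (mu_j T + cv^2 mu_j^2 T^2)].
    """
    ai, aj = mu_i_hz * window_s, mu_j_hz * window_s
    num = cv ** 2 * ai * aj
    den = np.sqrt((ai + cv ** 2 * ai ** 2) * (aj + cv ** 2 * aj ** 2))
    return float(num / den)


def coupling_values(results: list) -> np.ndarray:
    """Finite coupling values from a CouplingResult list."""
    return np.array([r.coupling_hz for r in results
                     if r.coupling_hz is not None])
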