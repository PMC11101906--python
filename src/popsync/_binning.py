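"""Internal helpers: epoch windows and spike binning.

An *epoch* is a list of ``(t0, t1)`` windows in seconds.  Binned analyses
concatenate the windows' count vectors; lagged statistics never straddle a
window boundary.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

Windows = List[Tuple[float, float]]


def epoch_duration(windows: Windows) -> float:
    return float(sum(t1 - t0 for t0, t1 in windows))


def count_in_windows(spike_times: np.ndarray, windows: Windows) -> int:
    t = np.asarray(spike_times)
    n = 0
    for t0, t1 in windows:
        n += int(np.searchsorted(t, t1) - np.searchsorted(t, t0))
    return n


def bin_windows(spike_times: np.ndarray, windows: Windows,
                bin_s: float):
    """Bin spikes within each window; return concatenated counts + slices.

    Each window is binned independently into ``floor(width / bin_s)`` bins
    (a partial trailing bin is discarded so all bins have equal width).
    Returns ``(counts, slices)`` where ``slices[k] = (start, n_bins)`` of
    window ``k`` inside the concatenated vector.
    """
    t = np.asarray(spike_times, dtype=float)
    parts, slices, start = [], [], 0
    for t0, t1 in windows:
        n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
        if n_bins == 0:
            slices.append((start, 0))
            continue
        edges = t0 + bin_s * np.arange(n_bins + 1)
        counts, _ = np.histogram(t, bins=edges)
        parts.append(counts)
        slices.append((start, n_bins))
        start += n_bins
    counts = (np.concatenate(parts) if parts
              else np.zeros(0, dtype=np.int64))
    return counts.astype(np.int64), slices


def bin_session(session, windows: Windows, bin_s: float):
    """Counts matrix (n_units, n_bins) over a concatenated epoch."""
    mats, slices = [], None
    for train, _ in session.units:
        c, slices = bin_windows(train.spike_times, windows, bin_s)
        mats.append(c)
    return np.vstack(mats), slices


def indentation_windows(session, parts: Sequence[str] = ("on", "off", "sustained"),
                        on_ms: float = 50.0, off_ms: float = 50.0,
                        sustained_ms: float = 200.0) -> Windows:
    """Evoked response windows around each indentation step.

    ON = [onset, onset+50 ms]; OFF = [offset, offset+50 ms];
    SUSTAINED = [offset-200 ms, offset].
    """
    wins: Windows = []
    for ev in session.events_of("indentation"):
        for p in parts:
            if p == "on":
                wins.append((ev.onset_s, ev.onset_s + on_ms / 1e3))
            elif p == "off":
                wins.append((ev.offset_s, ev.offset_s + off_ms / 1e3))
            elif p == "sustained":
                wins.append((ev.offset_s - sustained_ms / 1e3, ev.offset_s))
            elif p == "full":
                wins.append((ev.onset_s, ev.offset_s))
            else:
                raise ValueError(f"unknown window part {p!r}")
    wins.sort()
    return wins


def baseline_windows(session, baseline_s: float = 1.5) -> Windows:
    """Per-trial pre-stimulus baselines (spontaneous activity windows)."""
    return sorted((ev.onset_s - baseline_s, ev.onset_s)
                  for ev in session.events_of("indentation"))


def brush_windows(session) -> Windows:
    return sorted((ev.onset_s, ev.offset_s) for ev in session.events_of("brush"))
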