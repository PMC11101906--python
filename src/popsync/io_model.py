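"""Session data model and on-disk formats.

A recording session bundles sorted single units (spike-time arrays plus
metadata such as electrode depth), a typed stimulus-event table
(indentation force steps, brush epochs, light pulses), and an optional
multichannel LFP trace.  Every analysis stage consumes a validated
:class:`Session`; nothing downstream touches raw files.

All times are seconds (float64) internally.  Milliseconds appear only in
user-facing parameters and are converted at the boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Recording sampling rate assumed for duplicate-spike resolution (20 kHz).
SAMPLING_RESOLUTION_S = 50e-6

#: Default superficial/deep dorsal-horn boundary, micrometers below surface.
DEFAULT_DEPTH_BOUNDARY_UM = 240.0

#: Deepest recorded unit the model admits (dorsal horn span).
MAX_DEPTH_UM = 620.0


class ValidationError(ValueError):
    """Raised when a session component violates a model invariant."""


class SchemaError(ValueError):
    """Raised when an on-disk table lacks a required column."""


@dataclass
class SpikeTrain:
    """One unit's sorted spike times.

    Parameters
    ----------
    unit_id : str
    spike_times : array of float
        Seconds, strictly ascending, non-negative, all below ``t_stop``.
    t_stop : float
        Recording duration in seconds.
    """

    unit_id: str
    spike_times: np.ndarray
    t_stop: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if self.spike_times.size:
            if self.spike_times[0] < 0:
                raise ValidationError(f"unit {self.unit_id}: negative spike time")
            d = np.diff(self.spike_times)
            if np.any(d <= 0):
                raise ValidationError(
                    f"unit {self.unit_id}: spike times not strictly ascending"
                )
            if np.any(d < SAMPLING_RESOLUTION_S):
                raise ValidationError(
                    f"unit {self.unit_id}: duplicate spikes at 20 kHz resolution"
                )
            if self.spike_times[-1] >= self.t_stop:
                raise ValidationError(
                    f"unit {self.unit_id}: spike time >= t_stop ({self.t_stop})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate_hz(self) -> float:
        return self.n_spikes / self.t_stop if self.t_stop > 0 else np.nan


@dataclass
class UnitMeta:
    """Per-unit metadata: electrode depth, channel, optional waveform/tag."""

    unit_id: str
    depth_um: float
    channel: int = 0
    mean_waveform: Optional[np.ndarray] = None
    opto_label: str = "untagged"  # untagged | tagged | excluded

    def __post_init__(self) -> None:
        if not (0 <= self.depth_um <= MAX_DEPTH_UM):
            raise ValidationError(
                f"unit {self.unit_id}: depth_um {self.depth_um} outside "
                f"[0, {MAX_DEPTH_UM}]"
            )
        if self.opto_label not in ("untagged", "tagged", "excluded"):
            raise ValidationError(
                f"unit {self.unit_id}: bad opto_label {self.opto_label!r}"
            )

    def stratum(self, boundary_um: float = DEFAULT_DEPTH_BOUNDARY_UM) -> str:
        """Depth stratum, half-open: superficial = [0, boundary)."""
        return "superficial" if self.depth_um < boundary_um else "deep"


EVENT_KINDS = ("indentation", "brush", "light")


@dataclass
class StimulusEvent:
    """A typed stimulus epoch: indentation step, brush epoch, or light pulse."""

    kind: str
    onset_s: float
    offset_s: float
    trial_index: int
    force_mN: Optional[float] = None  # indentation only
    block: Optional[str] = None       # light only: pre_blocker | post_blocker

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(
                f"trial {self.trial_index}: unknown event kind {self.kind!r}"
            )
        if self.offset_s <= self.onset_s:
            raise ValidationError(
                f"trial {self.trial_index}: offset_s <= onset_s"
            )
        if self.kind == "indentation":
            if self.force_mN is None:
                raise ValidationError(
                    f"trial {self.trial_index}: indentation needs force_mN"
                )
            if not (1.0 <= self.force_mN <= 75.0):
                raise ValidationError(
                    f"trial {self.trial_index}: force {self.force_mN} mN outside "
                    "the innocuous range [1, 75]"
                )
        if self.kind == "light" and self.block not in (
            "pre_blocker", "post_blocker", None
        ):
            raise ValidationError(
                f"trial {self.trial_index}: bad light block {self.block!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Session:
    """One recording session: units, events, optional LFP.

    ``lfp`` is a ``(traces, fs_hz)`` tuple with ``traces`` shaped
    (channels, samples), or None.
    """

    session_id: str
    units: list  # list of (SpikeTrain, UnitMeta)
    events: list  # list of StimulusEvent
    condition: str = ""
    lfp: Optional[tuple] = None
    ground_truth: Optional["GroundTruth"] = None

    def __post_init__(self) -> None:
        if not self.units:
            raise ValidationError(f"session {self.session_id}: needs >=1 unit")
        t_min = min(tr.t_stop for tr, _ in self.units)
        for ev in self.events:
            if ev.onset_s < 0 or ev.offset_s > t_min:
                raise ValidationError(
                    f"session {self.session_id}: event trial {ev.trial_index} "
                    f"outside [0, {t_min}]"
                )
        # events must not overlap within a kind
        for kind in EVENT_KINDS:
            evs = sorted(self.events_of(kind), key=lambda e: e.onset_s)
            for a, b in zip(evs, evs[1:]):
                if b.onset_s < a.offset_s:
                    raise ValidationError(
                        f"session {self.session_id}: overlapping {kind} events "
                        f"(trials {a.trial_index}, {b.trial_index})"
                    )

    # -- convenience ---------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list:
        return [m.unit_id for _, m in self.units]

    def events_of(self, kind: str, force_mN: Optional[float] = None,
                  block: Optional[str] = None) -> list:
        out = [e for e in self.events if e.kind == kind]
        if force_mN is not None:
            out = [e for e in out if e.force_mN == force_mN]
        if block is not None:
            out = [e for e in out if e.block == block]
        return out

    def forces(self) -> list:
        return sorted({e.force_mN for e in self.events_of("indentation")})

    def subset(self, unit_ids: Sequence[str]) -> "Session":
        keep = set(unit_ids)
        units = [(tr, m) for tr, m in self.units if m.unit_id in keep]
        return Session(self.session_id, units, list(self.events),
                       condition=self.condition, lfp=self.lfp,
                       ground_truth=self.ground_truth)


@dataclass
class GroundTruth:
    """Generator parameters recorded alongside a synthetic session.

    Arrays are per-unit, ordered like ``Session.units``.
    """

    unit_ids: list
    p_event: list            # per-unit population-event participation, [0, 1]
    threshold_mN: list
    a_on_hz: list
    a_sus_hz: list
    a_off_hz: list
    baseline_hz: list
    latency_ms: list
    latency_sd_ms: list
    depth_um: list
    gain_cv: float
    sigma_sync_ms: float
    rho_tuning: float
    rng_seed: int
    tuning_template_id: str = "shared-saturating"

    def __post_init__(self) -> None:
        if any(not (0.0 <= p <= 1.0) for p in self.p_event):
            raise ValidationError("p_event outside [0, 1]")
        for name in ("a_on_hz", "a_sus_hz", "a_off_hz", "baseline_hz"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValidationError(f"{name} must be >= 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# session directory I/O
# ---------------------------------------------------------------------------

def save_session(session: Session, path) -> None:
    """Write a Session as a plain-text session directory.

    Layout: ``units/<unit_id>.csv`` (column ``spike_time_s``),
    ``unit_meta.csv``, ``events.csv``, optional ``lfp.h5`` and
    ``ground_truth.json``.
    """
    path = Path(path)
    (path / "units").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for tr, m in session.units:
        pd.DataFrame({"spike_time_s": tr.spike_times}).to_csv(
            path / "units" / f"{m.unit_id}.csv", index=False
        )
        meta_rows.append(
            {"unit_id": m.unit_id, "depth_um": m.depth_um,
             "channel": m.channel, "t_stop_s": tr.t_stop,
             "opto_label": m.opto_label}
        )
    pd.DataFrame(meta_rows).to_csv(path / "unit_meta.csv", index=False)
    ev_rows = [
        {"kind": e.kind, "onset_s": e.onset_s, "offset_s": e.offset_s,
         "force_mN": "" if e.force_mN is None else e.force_mN,
         "block": "" if e.block is None else e.block,
         "trial_index": e.trial_index}
        for e in session.events
    ]
    pd.DataFrame(
        ev_rows,
        columns=["kind", "onset_s", "offset_s", "force_mN", "block",
                 "trial_index"],
    ).to_csv(path / "events.csv", index=False)
    (path / "session.json").write_text(json.dumps(
        {"session_id": session.session_id, "condition": session.condition}
    ))
    if session.lfp is not None:
        import h5py

        traces, fs = session.lfp
        with h5py.File(path / "lfp.h5", "w") as f:
            d = f.create_dataset("traces", data=np.asarray(traces))
            d.attrs["fs_hz"] = float(fs)
    if session.ground_truth is not None:
        session.ground_truth.to_json(path / "ground_truth.json")


_REQUIRED_META = ("unit_id", "depth_um", "channel")
_REQUIRED_EVENTS = ("kind", "onset_s", "offset_s", "trial_index")


def load_session(path, schema: Optional[dict] = None) -> Session:
    """Load and validate a session directory written by :func:`save_session`.

    ``schema`` may rename columns, e.g. ``{"spike_time": "spike_time_s"}``
    maps an on-disk column to the canonical name.
    """
    path = Path(path)
    rename = {v: k for k, v in (schema or {}).items()} or {}

    meta_df = pd.read_csv(path / "unit_meta.csv", float_precision="round_trip").rename(columns=rename)
    for col in _REQUIRED_META:
        if col not in meta_df.columns:
            raise SchemaError(f"unit_meta.csv missing column {col!r}")

    ev_df = pd.read_csv(path / "events.csv", float_precision="round_trip").rename(columns=rename)
    for col in _REQUIRED_EVENTS:
        if col not in ev_df.columns:
            raise SchemaError(f"events.csv missing column {col!r}")

    units = []
    for row in meta_df.itertuples():
        f = path / "units" / f"{row.unit_id}.csv"
        sp = pd.read_csv(f, float_precision="round_trip").rename(columns=rename)
        if "spike_time_s" not in sp.columns:
            raise SchemaError(f"{f.name} missing column 'spike_time_s'")
        t_stop = float(getattr(row, "t_stop_s", np.nan))
        times = sp["spike_time_s"].to_numpy(dtype=float)
        if np.isnan(t_stop):
            t_stop = float(times[-1]) + 1.0 if times.size else 1.0
        train = SpikeTrain(str(row.unit_id), times, t_stop)
        meta = UnitMeta(str(row.unit_id), float(row.depth_um),
                        int(row.channel),
                        opto_label=str(getattr(row, "opto_label", "untagged")))
        units.append((train, meta))

    events = []
    for row in ev_df.itertuples():
        force = getattr(row, "force_mN", None)
        force = None if force is None or pd.isna(force) or force == "" else float(force)
        block = getattr(row, "block", None)
        block = None if block is None or pd.isna(block) or block == "" else str(block)
        events.append(StimulusEvent(str(row.kind), float(row.onset_s),
                                    float(row.offset_s), int(row.trial_index),
                                    force_mN=force, block=block))

    sid, cond = path.name, ""
    sj = path / "session.json"
    if sj.exists():
        d = json.loads(sj.read_text())
        sid, cond = d.get("session_id", sid), d.get("condition", cond)

    lfp = None
    if (path / "lfp.h5").exists():
        import h5py

        with h5py.File(path / "lfp.h5", "r") as f:
            lfp = (f["traces"][...], float(f["traces"].attrs["fs_hz"]))

    gt = None
    if (path / "ground_truth.json").exists():
        gt = GroundTruth.from_json(path / "ground_truth.json")

    return Session(sid, units, events, condition=cond, lfp=lfp,
                   ground_truth=gt)


def import_sorter_export(path, fs_hz: float) -> list:
    """Read a spike-sorter export into SpikeTrains (single units only).

    Expects ``spike_samples`` and ``spike_clusters`` parallel integer arrays
    (``.npy`` or single-column text) and ``cluster_labels.csv`` with columns
    ``cluster_id,label`` where label ``single`` marks well-isolated units.
    Multi-unit clusters are dropped and counted in the log.  Empty single-unit
    clusters are kept with zero spikes and flagged in the log.
    """
    path = Path(path)

    def _read_array(stem: str) -> np.ndarray:
        npy, txt = path / f"{stem}.npy", path / f"{stem}.csv"
        if npy.exists():
            return np.load(npy).ravel().astype(np.int64)
        if txt.exists():
            return np.loadtxt(txt, dtype=np.int64, ndmin=1)
        raise FileNotFoundError(f"neither {stem}.npy nor {stem}.csv in {path}")

    samples = _read_array("spike_samples")
    clusters = _read_array("spike_clusters")
    if samples.shape != clusters.shape:
        raise ValidationError(
            f"spike_samples ({samples.size}) and spike_clusters "
            f"({clusters.size}) lengths differ"
        )
    labels = pd.read_csv(path / "cluster_labels.csv")
    t_stop = (samples.max() / fs_hz + 1.0) if samples.size else 1.0

    trains, n_dropped = [], 0
    for row in labels.itertuples():
        if str(row.label) != "single":
            n_dropped += 1
            continue
        t = np.sort(samples[clusters == row.cluster_id]) / fs_hz
        # collapse duplicates at the sampling resolution
        if t.size > 1:
            t = t[np.concatenate([[True], np.diff(t) >= SAMPLING_RESOLUTION_S])]
        if t.size == 0:
            log.warning("cluster %s labeled single but has no spikes",
                        row.cluster_id)
        trains.append(SpikeTrain(f"unit{row.cluster_id}", t, t_stop))
    if n_dropped:
        log.info("dropped %d multi-unit clusters", n_dropped)
    return trains


def save_results(results, path, config: Optional[dict] = None,
                 seed: Optional[int] = None) -> None:
    """Write a tidy result table plus a JSON sidecar with config and seed.

    ``results`` is a DataFrame or a list of dataclass instances (one row per
    unit or pair).
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = [asdict(r) if not isinstance(r, dict) else r for r in results]
        df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn(f"writing header-only table to {path}")
    df.to_csv(path, index=False)
    sidecar = {"config": config or {}, "seed": seed, "version": __version__}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
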