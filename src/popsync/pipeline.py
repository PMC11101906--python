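"""Config-driven end-to-end runs and group-level phenotype contrasts.

A pipeline config names input sessions (directories) or a synthetic
preset with seeds, the stages to run, the per-stage parameters, and an
output directory.  Stages run in the order tuning -> correlations ->
timing -> signals -> behavior; each writes a tidy per-unit or per-pair
table plus a JSON sidecar carrying the config and seed, so identical
configs reproduce outputs byte for byte.

``phenotype_contrast`` compares two groups of sessions on summary metrics
(population coupling, sustained rates, thresholds, pairwise synchrony)
with rank-sum tests and direction flags; it asserts effect directions,
not magnitudes.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import behavior, correlations, signals, timing, tuning
from .io_model import Session, load_session, save_results
from .synthetic import preset_condition

log = logging.getLogger(__name__)

STAGES = ("tuning", "correlations", "timing", "signals", "behavior")
CONTRAST_METRICS = ("coupling", "sustained_rate", "threshold", "sync_r")


class StageError(RuntimeError):
    def __init__(self, stage: str, session_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on session "
                         f"{session_id!r}: {cause}")
        self.stage, self.session_id = stage, session_id


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    cfg.setdefault("stages", list(STAGES))
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    if "sessions" not in cfg and "preset" not in cfg:
        raise ValueError("config needs 'sessions' (paths) or 'preset'")
    cfg.setdefault("out_dir", "results")
    cfg.setdefault("params", {})
    return cfg


def _load_inputs(cfg: dict) -> list:
    if "sessions" in cfg:
        return [load_session(p) for p in cfg["sessions"]]
    p = cfg["preset"]
    n = int(p.get("n_sessions", 1))
    return [preset_condition(p["name"], int(cfg["seed"]) + k)[0]
            for k in range(n)]


def _stage_tuning(session: Session, out: Path, seed: int, params: dict):
    rows = []
    events = session.events_of("indentation")
    for train, meta in session.units:
        tc = tuning.tuning_curve(train, events,
                                 n_boot=params.get("n_boot", 1000),
                                 seed=seed)
        top = -1  # strongest force
        rows.append({
            "unit_id": meta.unit_id, "depth_um": meta.depth_um,
            "baseline_hz": tc.baseline_hz, "threshold_mN": tc.threshold_mN,
            "on_hz_top": tc.on_hz[top], "off_hz_top": tc.off_hz[top],
            "sustained_hz_top": tc.sustained_hz[top],
        })
    save_results(pd.DataFrame(rows), out / "tuning.csv", params, seed)


def _stage_correlations(session: Session, out: Path, seed: int, params: dict):
    bin_ms = params.get("bin_ms", 1.0)
    epoch = params.get("epoch", "evoked")
    res = correlations.population_coupling(
        session, bin_ms=bin_ms, epoch=epoch,
        n_shuffles=params.get("n_shuffles", 100), seed=seed)
    coup = pd.DataFrame([{
        "unit_id": r.unit_id, "coupling_hz": r.coupling_hz,
        "stpr_lag0_hz": r.stpr_lag0_hz,
        "shuffle_median_hz": r.shuffle_median_hz, "bin_ms": r.bin_ms,
        "stratum": r.stratum, "epoch": r.epoch} for r in res])
    save_results(coup, out / "coupling.csv", params, seed)

    sync = correlations.pairwise_synchrony(session, bin_ms=bin_ms,
                                           epoch="full_step", with_ccg=False)
    noise = correlations.noise_correlations(session)
    sig = correlations.signal_correlations(session)
    pairs = pd.DataFrame([{
        "unit_a": s.unit_a, "unit_b": s.unit_b, "sync_r": s.sync_r,
        "noise_r": n.noise_r, "signal_r": g.signal_r}
        for s, n, g in zip(sync, noise, sig)])
    save_results(pairs, out / "pairs.csv", params, seed)


def _stage_timing(session: Session, out: Path, seed: int, params: dict):
    rows = []
    for force in params.get("forces", (10.0, 75.0)):
        events = session.events_of("indentation", force_mN=force)
        for train, meta in session.units:
            if len(events) < timing.MIN_TRIALS:
                rows.append({"unit_id": meta.unit_id, "force_mN": force,
                             "latency_ms": None, "jitter_ms": None,
                             "n_trials": len(events),
                             "reason": "fewer than 50 trials"})
                continue
            r = timing.latency_and_jitter(train, events, seed=seed)
            rows.append({"unit_id": r.unit_id, "force_mN": r.force_mN,
                         "latency_ms": r.latency_ms, "jitter_ms": r.jitter_ms,
                         "n_trials": r.n_trials, "reason": ""})
    save_results(pd.DataFrame(rows), out / "latency.csv", params, seed)


def _stage_signals(session: Session, out: Path, seed: int, params: dict):
    if session.lfp is not None:
        traces, fs = session.lfp
        res = signals.lfp_spectrum(traces, fs,
                                   band=tuple(params.get("band", (30, 80))))
        df = pd.DataFrame({"freq_hz": res.freqs_hz, "psd": res.psd_mean})
        df.attrs["relative_band_power"] = res.relative_band_power
        save_results(df, out / "lfp_psd.csv",
                     {**params,
                      "relative_band_power": res.relative_band_power}, seed)
    feats = []
    for train, meta in session.units:
        if meta.mean_waveform is not None:
            feats.append(signals.waveform_features(
                meta.mean_waveform, 20_000.0, unit_id=meta.unit_id))
    if len(feats) >= 3:
        signals.cluster_waveforms(feats, seed=seed)
        save_results(pd.DataFrame([dataclasses.asdict(f) for f in feats]),
                     out / "waveforms.csv", params, seed)
    pre = session.events_of("light", block="pre_blocker")
    post = session.events_of("light", block="post_blocker")
    if pre and post:
        rows = []
        for train, meta in session.units:
            r = signals.classify_optotag(train, pre, post, seed=seed)
            rows.append(dataclasses.asdict(r))
        save_results(pd.DataFrame(rows), out / "optotag.csv", params, seed)


def _stage_behavior(session: Session, out: Path, seed: int, params: dict):
    path = params.get("behavior_csv")
    if not path:
        return
    sheets = behavior.load_behavior_table(pd.read_csv(path))
    rows = [{"mouse_id": s.mouse_id, "allodynia_score": s.allodynia_score,
             "allodynic": s.allodynic} for s in sheets]
    save_results(pd.DataFrame(rows), out / "behavior.csv", params, seed)


_STAGE_FNS = {"tuning": _stage_tuning, "correlations": _stage_correlations,
              "timing": _stage_timing, "signals": _stage_signals,
              "behavior": _stage_behavior}


def run_pipeline(config: dict) -> dict:
    """Run the configured stages over every input session.

    Returns ``{session_id: output_dir}``.  A stage failure aborts with
    :class:`StageError`; outputs written so far are retained alongside a
    ``FAILED`` marker naming the stage and session.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    out_root = Path(cfg["out_dir"])
    sessions = _load_inputs(cfg)
    done = {}
    for sess in sessions:
        out = out_root / sess.session_id
        out.mkdir(parents=True, exist_ok=True)
        for stage in cfg["stages"]:
            params = dict(cfg["params"].get(stage, {}))
            try:
                _STAGE_FNS[stage](sess, out, seed, params)
            except Exception as exc:  # noqa: BLE001 - marker then re-raise
                (out / "FAILED").write_text(f"{stage}: {exc}\n")
                raise StageError(stage, sess.session_id, exc) from exc
        done[sess.session_id] = str(out)
    log.info("pipeline complete: %d sessions, seed %d", len(done), seed)
    return done


# ---------------------------------------------------------------------------
# group-level contrasts
# ---------------------------------------------------------------------------

def session_metrics(session: Session, seed: int,
                    metrics: Sequence[str] = CONTRAST_METRICS,
                    stratum: str = "all", n_boot: int = 200,
                    n_shuffles: int = 50) -> dict:
    """Session-level summary metrics used by :func:`phenotype_contrast`.

    coupling: mean normalized coupling over units (evoked epoch);
    sustained_rate: mean baseline-subtracted sustained rate at the top
    force; threshold: session mean of per-unit thresholds (None excluded);
    sync_r: mean pairwise lag-0 synchrony.
    """
    out = {}
    events = session.events_of("indentation")
    if "coupling" in metrics:
        res = correlations.population_coupling(
            session, epoch="evoked", stratum=stratum,
            n_shuffles=n_shuffles, seed=seed)
        vals = correlations.coupling_values(res)
        out["coupling"] = float(vals.mean()) if vals.size else np.nan
    if "sustained_rate" in metrics:
        top = max(session.forces())
        evs = session.events_of("indentation", force_mN=top)
        rates = [tuning.window_rates(tr, evs, subtract_baseline=True)
                 ["sustained_hz"] for tr, _ in session.units]
        out["sustained_rate"] = float(np.mean(rates))
    if "threshold" in metrics:
        ths = [tuning.detect_threshold(tr, events, n_boot=n_boot, seed=seed)
               for tr, _ in session.units]
        ths = [t for t in ths if t is not None]
        out["threshold"] = float(np.mean(ths)) if ths else np.nan
    if "sync_r" in metrics:
        pcs = correlations.pairwise_synchrony(session, epoch="full_step",
                                              with_ccg=False)
        rs = [p.sync_r for p in pcs if p.sync_r is not None]
        out["sync_r"] = float(np.mean(rs)) if rs else np.nan
    return out


def phenotype_contrast(sessions_a: Sequence[Session],
                       sessions_b: Sequence[Session], seed: int,
                       metrics: Sequence[str] = CONTRAST_METRICS,
                       stratum: str = "all",
                       alternative: str = "two-sided") -> pd.DataFrame:
    """Per-metric group comparison table for two session groups.

    Columns: metric, mean_a, mean_b, direction (sign of b - a), p
    (rank-sum, ``alternative`` applies to group a vs b).
    """
    if len(sessions_a) < 3 or len(sessions_b) < 3:
        raise ValueError("need at least 3 sessions per group")
    rows_a = [session_metrics(s, seed, metrics, stratum) for s in sessions_a]
    rows_b = [session_metrics(s, seed, metrics, stratum) for s in sessions_b]
    table = []
    for m in metrics:
        a = np.array([r[m] for r in rows_a])
        b = np.array([r[m] for r in rows_b])
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            raise ValueError(f"metric {m!r} missing in at least one session")
        res = behavior.compare_groups(a, b, method="rank_sum",
                                      alternative=alternative)
        table.append({"metric": m, "mean_a": a.mean(), "mean_b": b.mean(),
                      "direction": int(np.sign(b.mean() - a.mean())),
                      "p": res["p"]})
    return pd.DataFrame(table)
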