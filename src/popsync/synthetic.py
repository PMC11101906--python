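"""Synthetic session generator with recorded ground truth.

Sessions are built from two superimposed processes per unit:

* a **private inhomogeneous Poisson process** with rate
  ``lambda_i(tau) = g_t * [b_i + 1{F >= theta_i} * w_i(F) *
  (A_on * alpha_on(tau) + A_sus * box(tau) + A_off * alpha_off(tau))]``
  sampled by thinning, where ``g_t`` is a trial-shared lognormal gain and
  ``w_i(F)`` a per-unit force-tuning weight mixing a shared saturating
  template with a private one (mixing weight ``rho_tuning``);

* a **population-event process**: an event train drawn Poisson at a
  window-specific rate; at each event, unit ``i`` emits one spike with
  probability ``p_i`` at the event time plus Gaussian timing jitter
  ``sigma_sync``.  Conditional on the event train and the gains, units are
  independent, so the analytic moments of pairwise statistics are known.

Event spikes and private spikes are merged and deduplicated at the 20 kHz
sampling resolution (50 us).  All randomness flows from one seed through a
named-stream splitter, so adding units does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_model import (
    GroundTruth,
    Session,
    SpikeTrain,
    StimulusEvent,
    UnitMeta,
    SAMPLING_RESOLUTION_S,
)

PRESETS = ("sham_like", "sni_like", "pv_silenced_like", "psi_ko_like")


def stream(seed: int, *keys) -> np.random.Generator:
    """Named random stream: one root seed, independent per-key generators."""
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed),
                                                        spawn_key=spawn))


@dataclass
class ProtocolSpec:
    """Stimulus protocol: indentation steps, optional brush and light pulses.

    Indentation trials tile the timeline contiguously with period
    ``baseline_s + step_dur_s + post_s``; forces cycle round-robin through
    ``forces_mN`` so every force is sampled evenly across the recording.
    """

    forces_mN: Sequence[float] = (1.0, 5.0, 10.0, 20.0, 45.0, 75.0)
    step_dur_s: float = 0.5
    baseline_s: float = 1.5
    post_s: float = 0.5
    trials_per_force: int = 10
    brush_dur_s: float = 60.0
    n_light_pulses: int = 0
    light_width_ms: float = 5.0
    light_ipi_s: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.forces_mN, dtype=float)
        if np.any(f < 1.0) or np.any(f > 75.0):
            raise ValueError("forces must lie in the innocuous range [1, 75] mN")
        if np.any(np.diff(f) <= 0):
            raise ValueError("forces_mN must be strictly ascending")
        if self.baseline_s < 1.5:
            raise ValueError("baseline_s must be >= 1.5 s")
        if not (1.0 <= self.light_width_ms <= 20.0):
            raise ValueError("light_width_ms must be in [1, 20] ms")

    @property
    def trial_period_s(self) -> float:
        return self.baseline_s + self.step_dur_s + self.post_s

    @property
    def n_trials(self) -> int:
        return self.trials_per_force * len(self.forces_mN)


@dataclass
class PopulationSpec:
    """Generative parameters of the simulated population.

    Scalar fields broadcast to all units; sequence fields are per-unit.
    Rates in Hz, times in ms where named so, probabilities in [0, 1].
    """

    n_units: int = 16
    depths_um: Optional[Sequence[float]] = None  # default: uniform over [0, 620]
    baseline_hz: float | Sequence[float] = 5.0
    threshold_mN: float | Sequence[float] = 10.0
    a_on_hz: float | Sequence[float] = 40.0
    a_sus_hz: float | Sequence[float] = 20.0
    a_off_hz: float | Sequence[float] = 30.0
    tau_on_ms: float = 10.0
    tau_off_ms: float = 10.0
    a_brush_hz: float | Sequence[float] = 10.0
    p_event: float | Sequence[float] = 0.3
    sigma_sync_ms: float = 1.0
    event_rate_on_hz: float = 30.0
    event_rate_sustained_hz: float = 8.0
    event_rate_off_hz: float = 30.0
    event_rate_brush_hz: float = 5.0
    gain_cv: float = 0.2
    rho_tuning: float = 0.5
    latency_ms: float | Sequence[float] = 10.0
    latency_sd_ms: float | Sequence[float] = 1.0
    opto_tagged: Optional[Sequence[bool]] = None
    opto_latency_ms: float = 3.0
    #: explicit (n_units, n_forces) force-tuning weights; overrides the
    #: rho-mixed shared/private templates when given
    tuning_weights: Optional[np.ndarray] = None
    #: force the first ON spike at Gaussian(latency, latency_sd) on
    #: supra-threshold trials (models the reliable ON transient)
    force_first_spike: bool = True

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_event, dtype=float))
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p_event must lie in [0, 1]")
        if not (0.0 <= self.rho_tuning <= 1.0):
            raise ValueError("rho_tuning must lie in [0, 1]")
        for name in ("baseline_hz", "a_on_hz", "a_sus_hz", "a_off_hz",
                     "a_brush_hz"):
            if np.any(np.atleast_1d(np.asarray(getattr(self, name))) < 0):
                raise ValueError(f"{name} must be >= 0")

    def per_unit(self, name: str) -> np.ndarray:
        v = np.asarray(getattr(self, name), dtype=float)
        return np.broadcast_to(v, (self.n_units,)).copy()


def _alpha(tau: np.ndarray, tau_peak_s: float) -> np.ndarray:
    """Alpha kernel, peak 1 at tau_peak, zero for tau < 0."""
    out = np.zeros_like(tau)
    m = tau > 0
    x = tau[m] / tau_peak_s
    out[m] = x * np.exp(1.0 - x)
    return out


def _dedup(times: np.ndarray, t_stop: float) -> np.ndarray:
    """Sort, clip to [0, t_stop), drop spikes closer than 50 us."""
    t = np.sort(times)
    t = t[(t >= 0) & (t < t_stop)]
    if t.size < 2:
        return t
    keep = np.concatenate([[True], np.diff(t) >= SAMPLING_RESOLUTION_S])
    return t[keep]


def _thin_poisson(rng: np.random.Generator, t0: float, t1: float,
                  rate_fn, rate_max: float) -> np.ndarray:
    """Inhomogeneous Poisson by thinning over [t0, t1)."""
    if rate_max <= 0:
        return np.zeros(0)
    n = rng.poisson(rate_max * (t1 - t0))
    if n == 0:
        return np.zeros(0)
    t = t0 + rng.random(n) * (t1 - t0)
    keep = rng.random(n) * rate_max < rate_fn(t)
    return t[keep]


def simulate_session(protocol: ProtocolSpec, pop: PopulationSpec,
                     seed: int, session_id: str = "synthetic",
                     condition: str = "synthetic"):
    """Simulate one session; returns ``(Session, GroundTruth)``.

    Identical ``(protocol, pop, seed)`` give byte-identical spike times.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    n = pop.n_units
    forces = np.asarray(protocol.forces_mN, dtype=float)

    b = pop.per_unit("baseline_hz")
    theta = pop.per_unit("threshold_mN")
    a_on = pop.per_unit("a_on_hz")
    a_sus = pop.per_unit("a_sus_hz")
    a_off = pop.per_unit("a_off_hz")
    a_brush = pop.per_unit("a_brush_hz")
    p_ev = pop.per_unit("p_event")
    mu_lat = pop.per_unit("latency_ms") / 1e3
    sd_lat = pop.per_unit("latency_sd_ms") / 1e3
    tau_on = pop.tau_on_ms / 1e3
    tau_off = pop.tau_off_ms / 1e3
    sig_sync = pop.sigma_sync_ms / 1e3

    if pop.depths_um is not None:
        depths = np.asarray(pop.depths_um, dtype=float)
        if depths.size != n:
            raise ValueError("depths_um length must equal n_units")
    else:
        depths = stream(seed, "depths").uniform(0.0, 620.0, size=n)

    # force-tuning weights: rho-weighted mix of shared and private templates,
    # normalized to unit mean so amplitudes keep their Hz meaning
    if pop.tuning_weights is not None:
        w = np.asarray(pop.tuning_weights, dtype=float)
        if w.shape != (n, forces.size):
            raise ValueError("tuning_weights must be (n_units, n_forces)")
    else:
        shared = forces / (forces + 15.0)
        shared = shared / shared.mean()
        w = np.empty((n, forces.size))
        for i in range(n):
            priv = stream(seed, "tuning", i).lognormal(0.0, 0.5,
                                                       size=forces.size)
            priv = priv / priv.mean()
            wi = pop.rho_tuning * shared + (1.0 - pop.rho_tuning) * priv
            w[i] = wi / wi.mean()

    # ---- event schedule ---------------------------------------------------
    period = protocol.trial_period_s
    n_trials = protocol.n_trials
    events = []
    trial_force = np.empty(n_trials)
    trial_onset = np.empty(n_trials)
    for k in range(n_trials):
        f = forces[k % forces.size]
        onset = k * period + protocol.baseline_s
        trial_force[k] = f
        trial_onset[k] = onset
        events.append(StimulusEvent("indentation", onset,
                                    onset + protocol.step_dur_s, k, force_mN=f))
    t_cursor = n_trials * period
    trial_idx = n_trials
    brush_win = None
    if protocol.brush_dur_s > 0:
        brush_win = (t_cursor, t_cursor + protocol.brush_dur_s)
        events.append(StimulusEvent("brush", *brush_win, trial_idx))
        trial_idx += 1
        t_cursor = brush_win[1]
    light_times = {"pre_blocker": [], "post_blocker": []}
    if protocol.n_light_pulses > 0:
        for block in ("pre_blocker", "post_blocker"):
            t_cursor += 1.0
            for _ in range(protocol.n_light_pulses):
                on = t_cursor
                events.append(StimulusEvent(
                    "light", on, on + protocol.light_width_ms / 1e3,
                    trial_idx, block=block))
                light_times[block].append(on)
                trial_idx += 1
                t_cursor += protocol.light_ipi_s
    t_stop = t_cursor + 1.0

    # trial-shared gain
    if pop.gain_cv > 0:
        s2 = np.log1p(pop.gain_cv ** 2)
        gains = stream(seed, "gain").lognormal(-s2 / 2, np.sqrt(s2), n_trials)
    else:
        gains = np.ones(n_trials)

    # population-event train (window-specific rates)
    ev_rng = stream(seed, "events")
    pop_events = []
    step = protocol.step_dur_s
    for k in range(n_trials):
        on = trial_onset[k]
        for (t0, t1, r) in (
            (on, on + 0.05, pop.event_rate_on_hz),
            (on + step - 0.2, on + step, pop.event_rate_sustained_hz),
            (on + step, on + step + 0.05, pop.event_rate_off_hz),
        ):
            m = ev_rng.poisson(r * (t1 - t0))
            if m:
                pop_events.append(t0 + ev_rng.random(m) * (t1 - t0))
    if brush_win is not None and pop.event_rate_brush_hz > 0:
        m = ev_rng.poisson(pop.event_rate_brush_hz *
                           (brush_win[1] - brush_win[0]))
        if m:
            pop_events.append(brush_win[0] + ev_rng.random(m) *
                              (brush_win[1] - brush_win[0]))
    pop_events = (np.sort(np.concatenate(pop_events)) if pop_events
                  else np.zeros(0))
    # trial index of each event (-1 for brush-epoch events): a unit only
    # participates in stimulus-locked events on trials it responds to
    ev_trial = np.floor(pop_events / period).astype(int)
    ev_trial[pop_events >= n_trials * period] = -1

    opto_tagged = (np.zeros(n, dtype=bool) if pop.opto_tagged is None
                   else np.asarray(pop.opto_tagged, dtype=bool))

    # ---- per-unit spike generation ---------------------------------------
    units = []
    for i in range(n):
        rng = stream(seed, "private", i)
        pieces = []
        responds = trial_force >= theta[i]
        wi = {f: w[i, j] for j, f in enumerate(forces)}
        for k in range(n_trials):
            t0, t1 = k * period, (k + 1) * period
            on = trial_onset[k]
            g = gains[k]
            if responds[k]:
                wk = wi[trial_force[k]]

                def rate(t, on=on, g=g, wk=wk):
                    tau = t - on
                    r = (a_on[i] * _alpha(tau, tau_on)
                         + a_sus[i] * ((tau > 0) & (tau <= step))
                         + a_off[i] * _alpha(tau - step, tau_off))
                    return g * (b[i] + wk * r)

                rmax = g * (b[i] + wk * (a_on[i] + a_sus[i] + a_off[i]))
            else:
                def rate(t, g=g):
                    return np.full_like(t, g * b[i])

                rmax = g * b[i]
            pieces.append(_thin_poisson(rng, t0, t1, rate, rmax))
        # background + brush response during brush epoch
        if brush_win is not None:
            def rate(t):
                return np.full_like(t, b[i] + a_brush[i])

            pieces.append(_thin_poisson(stream(seed, "brush", i), *brush_win,
                                        rate, b[i] + a_brush[i]))
        # background after the indentation block
        tail0 = brush_win[1] if brush_win is not None else n_trials * period

        def rate(t):
            return np.full_like(t, b[i])

        pieces.append(_thin_poisson(stream(seed, "tail", i), tail0, t_stop,
                                    rate, b[i]))

        # population-event spikes
        if pop_events.size:
            er = stream(seed, "event_spikes", i)
            take = er.random(pop_events.size) < p_ev[i]
            jit = er.normal(0.0, sig_sync, size=pop_events.size)
            drivable = (ev_trial < 0) | responds[np.clip(ev_trial, 0, None)]
            take &= drivable
            pieces.append(pop_events[take] + jit[take])

        # light-evoked spikes for opto-tagged units (both blocks)
        if opto_tagged[i]:
            lr = stream(seed, "light", i)
            for block in ("pre_blocker", "post_blocker"):
                for on in light_times[block]:
                    if lr.random() < 0.95:
                        pieces.append(np.array(
                            [on + pop.opto_latency_ms / 1e3
                             + lr.normal(0.0, 3e-4)]))

        t = np.concatenate(pieces) if pieces else np.zeros(0)

        # forced first ON spike at Gaussian(mu_i, sd_i) when the ON response
        # would otherwise start later
        lr = stream(seed, "latency", i)
        extra = []
        forced_trials = (np.nonzero(responds)[0] if pop.force_first_spike
                         else np.zeros(0, dtype=int))
        for k in forced_trials:
            L = lr.normal(mu_lat[i], sd_lat[i])
            L = min(max(L, 5e-4), 0.099)
            on = trial_onset[k]
            if not np.any((t > on) & (t <= on + L)):
                extra.append(on + L)
        if extra:
            t = np.concatenate([t, np.asarray(extra)])

        t = _dedup(t, t_stop)
        meta = UnitMeta(f"u{i:03d}", float(depths[i]), channel=i,
                        opto_label="tagged" if opto_tagged[i] else "untagged")
        units.append((SpikeTrain(meta.unit_id, t, t_stop), meta))

    gt = GroundTruth(
        unit_ids=[m.unit_id for _, m in units],
        p_event=p_ev.tolist(), threshold_mN=theta.tolist(),
        a_on_hz=a_on.tolist(), a_sus_hz=a_sus.tolist(),
        a_off_hz=a_off.tolist(), baseline_hz=b.tolist(),
        latency_ms=(mu_lat * 1e3).tolist(),
        latency_sd_ms=(sd_lat * 1e3).tolist(),
        depth_um=depths.tolist(), gain_cv=pop.gain_cv,
        sigma_sync_ms=pop.sigma_sync_ms, rho_tuning=pop.rho_tuning,
        rng_seed=int(seed))
    session = Session(session_id, units, events, condition=condition,
                      ground_truth=gt)
    return session, gt


def simulate_correlated_population(n_units: int, dur_s: float,
                                   base_rate_hz: float,
                                   p_event: float | Sequence[float],
                                   event_rate_hz: float,
                                   sigma_sync_ms: float = 1.0,
                                   slow_gain_cv: float = 0.0,
                                   gain_block_s: float = 1.0,
                                   seed: int = None,
                                   session_id: str = "events"):
    """Stationary population with injected millisecond synchrony.

    Background spiking is Poisson at ``base_rate_hz`` modulated by a shared
    piecewise-constant lognormal gain (one value per ``gain_block_s`` block,
    CV ``slow_gain_cv``); population events occur Poisson at
    ``event_rate_hz`` and recruit unit ``i`` with probability ``p_i`` at the
    event time plus ``N(0, sigma_sync)`` jitter.  Returns
    ``(Session, GroundTruth)``; the session carries no stimulus events —
    analyses should use the epoch ``[(0, dur_s)]``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    p = np.broadcast_to(np.asarray(p_event, dtype=float), (n_units,)).copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_event must lie in [0, 1]")
    sig = sigma_sync_ms / 1e3

    n_blocks = int(np.ceil(dur_s / gain_block_s))
    if slow_gain_cv > 0:
        s2 = np.log1p(slow_gain_cv ** 2)
        gains = stream(seed, "gain").lognormal(-s2 / 2, np.sqrt(s2), n_blocks)
    else:
        gains = np.ones(n_blocks)

    ev_rng = stream(seed, "events")
    n_ev = ev_rng.poisson(event_rate_hz * dur_s)
    ev_times = np.sort(ev_rng.random(n_ev) * dur_s)

    t_stop = dur_s
    depths = stream(seed, "depths").uniform(0.0, 620.0, size=n_units)
    units = []
    for i in range(n_units):
        rng = stream(seed, "bg", i)
        pieces = []
        for kb in range(n_blocks):
            t0 = kb * gain_block_s
            t1 = min(t0 + gain_block_s, dur_s)
            m = rng.poisson(base_rate_hz * gains[kb] * (t1 - t0))
            if m:
                pieces.append(t0 + rng.random(m) * (t1 - t0))
        if ev_times.size:
            er = stream(seed, "event_spikes", i)
            take = er.random(ev_times.size) < p[i]
            jit = er.normal(0.0, sig, size=ev_times.size)
            pieces.append(ev_times[take] + jit[take])
        t = _dedup(np.concatenate(pieces) if pieces else np.zeros(0), t_stop)
        meta = UnitMeta(f"u{i:03d}", float(depths[i]), channel=i)
        units.append((SpikeTrain(meta.unit_id, t, t_stop), meta))

    gt = GroundTruth(
        unit_ids=[m.unit_id for _, m in units],
        p_event=p.tolist(), threshold_mN=[np.nan] * n_units,
        a_on_hz=[0.0] * n_units, a_sus_hz=[0.0] * n_units,
        a_off_hz=[0.0] * n_units, baseline_hz=[base_rate_hz] * n_units,
        latency_ms=[np.nan] * n_units, latency_sd_ms=[np.nan] * n_units,
        depth_um=depths.tolist(), gain_cv=slow_gain_cv,
        sigma_sync_ms=sigma_sync_ms, rho_tuning=0.0, rng_seed=int(seed))
    return Session(session_id, units, [], condition="events",
                   ground_truth=gt), gt


def orthogonal_tuning_pairs(n_pairs: int, n_forces: int,
                            seed: int) -> np.ndarray:
    """Strictly positive force-tuning weight pairs, orthogonal after
    centering (zero expected signal correlation for flat-response units).

    Returns a (2*n_pairs, n_forces) weight matrix; rows 2k and 2k+1 form
    pair k.  Suitable for ``PopulationSpec.tuning_weights``.
    """
    rng = stream(seed, "ortho_tuning")
    W = np.empty((2 * n_pairs, n_forces))
    ones = np.ones(n_forces) / np.sqrt(n_forces)
    for k in range(n_pairs):
        M = rng.normal(size=(n_forces, 2))
        M -= np.outer(ones, ones @ M)      # project out the mean component
        Q, _ = np.linalg.qr(M)
        for j in range(2):
            v = Q[:, j]
            w = 1.0 + 0.45 * v / np.max(np.abs(v))
            W[2 * k + j] = w / w.mean()
    return W


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

#: Reference ("sham-like") parameters for the preset conditions.  Preset
#: perturbations are stated conventions for recovery testing, not estimates
#: of biological effect sizes.
PRESET_REFERENCE = dict(
    n_units=16, n_superficial=8, baseline_hz=6.0,
    a_on_hz=40.0, a_sus_hz=20.0, a_off_hz=30.0, a_brush_hz=10.0,
    p_event=0.4, sigma_sync_ms=1.0, gain_cv=0.2, rho_tuning=0.5,
    latency_ms=10.0, latency_sd_ms=1.0,
    threshold_choices=(5.0, 10.0, 20.0),
    trials_per_force=12, brush_dur_s=0.0,
)


def preset_condition(name: str, seed: int,
                     protocol: Optional[ProtocolSpec] = None):
    """Build a preset synthetic condition; returns ``(Session, GroundTruth)``.

    ``sham_like`` is the reference.  Relative to it:

    * ``sni_like`` — event participation halved for superficial units,
      sustained amplitude reduced 30%, latency SD doubled;
    * ``pv_silenced_like`` — baseline and evoked amplitudes raised 30%,
      event participation halved (all depths);
    * ``psi_ko_like`` — rates raised 30%, event participation raised 50%,
      thresholds lowered one force-list position.

    The same ``seed`` gives matched per-unit draws across presets, so e.g.
    every ``psi_ko_like`` threshold sits exactly one force step below its
    ``sham_like`` counterpart.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    ref = PRESET_REFERENCE
    protocol = protocol or ProtocolSpec(
        trials_per_force=ref["trials_per_force"],
        brush_dur_s=ref["brush_dur_s"])
    forces = np.asarray(protocol.forces_mN)
    n = ref["n_units"]
    n_sup = ref["n_superficial"]
    depths = np.concatenate([
        np.linspace(40.0, 230.0, n_sup),
        np.linspace(260.0, 600.0, n - n_sup),
    ])
    sup = depths < 240.0

    # matched across presets: same stream names, same draws
    th_idx = stream(seed, "theta").integers(0, len(ref["threshold_choices"]),
                                            size=n)
    choice_pos = np.array([int(np.searchsorted(forces, c))
                           for c in ref["threshold_choices"]])
    theta_pos = choice_pos[th_idx]

    b = np.full(n, ref["baseline_hz"])
    a_on = np.full(n, ref["a_on_hz"])
    a_sus = np.full(n, ref["a_sus_hz"])
    a_off = np.full(n, ref["a_off_hz"])
    p = np.full(n, ref["p_event"])
    lat_sd = np.full(n, ref["latency_sd_ms"])

    if name == "sni_like":
        p[sup] *= 0.5
        a_sus *= 0.7
        lat_sd *= 2.0
    elif name == "pv_silenced_like":
        b *= 1.3
        a_on, a_sus, a_off = a_on * 1.3, a_sus * 1.3, a_off * 1.3
        p *= 0.5
    elif name == "psi_ko_like":
        b *= 1.3
        a_on, a_sus, a_off = a_on * 1.3, a_sus * 1.3, a_off * 1.3
        p = np.minimum(p * 1.5, 1.0)
        theta_pos = np.maximum(theta_pos - 1, 0)

    pop = PopulationSpec(
        n_units=n, depths_um=depths, baseline_hz=b,
        threshold_mN=forces[theta_pos], a_on_hz=a_on, a_sus_hz=a_sus,
        a_off_hz=a_off, a_brush_hz=ref["a_brush_hz"], p_event=p,
        sigma_sync_ms=ref["sigma_sync_ms"], gain_cv=ref["gain_cv"],
        rho_tuning=ref["rho_tuning"], latency_ms=ref["latency_ms"],
        latency_sd_ms=lat_sd)
    return simulate_session(protocol, pop, seed, session_id=f"{name}_{seed}",
                            condition=name)


# ---------------------------------------------------------------------------
# waveforms and LFP
# ---------------------------------------------------------------------------

@dataclass
class WaveformClass:
    """Biphasic extracellular waveform template (trough then peak)."""

    trough_to_peak_ms: float = 0.5
    trough_amp_uv: float = 100.0
    peak_amp_uv: float = 40.0
    width_ms: float = 0.1


def waveform_template(cls: WaveformClass, fs_hz: float = 20_000.0,
                      n_samples: int = 64,
                      trough_sample: int = 16) -> np.ndarray:
    t = np.arange(n_samples) / fs_hz
    t_tr = trough_sample / fs_hz
    t_pk = t_tr + cls.trough_to_peak_ms / 1e3
    w = cls.width_ms / 1e3
    return (-cls.trough_amp_uv * np.exp(-((t - t_tr) ** 2) / (2 * w ** 2))
            + cls.peak_amp_uv * np.exp(-((t - t_pk) ** 2) / (2 * w ** 2)))


def simulate_waveforms(n_per_class: int, classes: Sequence[WaveformClass],
                       noise_sd: float, seed: int,
                       fs_hz: float = 20_000.0, n_samples: int = 64):
    """Labeled waveform set: template + white noise per class.

    Returns ``(waveforms (n, n_samples), labels (n,), fs_hz)``.
    """
    if not classes:
        raise ValueError("need at least one waveform class")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = stream(seed, "waveforms")
    wfs, labels = [], []
    for ci, cls in enumerate(classes):
        tmpl = waveform_template(cls, fs_hz, n_samples)
        for _ in range(n_per_class):
            wfs.append(tmpl + rng.normal(0.0, noise_sd, size=n_samples))
            labels.append(ci)
    return np.asarray(wfs), np.asarray(labels), fs_hz


def simulate_lfp(dur_s: float, fs_hz: float, one_over_f_amp: float = 1.0,
                 gamma_hz: Optional[float] = None, gamma_amp: float = 0.0,
                 f_min_hz: float = 1.0, seed: int = None) -> np.ndarray:
    """1/f-shaped Gaussian noise plus an optional gamma-band sinusoid.

    The noise PSD is proportional to ``1/f`` for ``f >= f_min_hz`` and zero
    below, so the analytic relative band power of the pure-noise trace over
    ``[f1, f2]`` against ``(f_min, f_hi]`` is ``ln(f2/f1) / ln(f_hi/f_min)``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    if fs_hz < 1000:
        raise ValueError("fs_hz must be >= 1000")
    if gamma_hz is not None and not (0.0 < gamma_hz < fs_hz / 2):
        raise ValueError("gamma_hz must lie in (0, fs/2)")
    n = int(round(dur_s * fs_hz))
    rng = stream(seed, "lfp")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    amp = np.zeros_like(freqs)
    m = freqs >= f_min_hz
    amp[m] = freqs[m] ** -0.5
    spec = amp * (rng.normal(size=freqs.size)
                  + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n)
    if one_over_f_amp > 0 and x.std() > 0:
        x = one_over_f_amp * x / x.std()
    else:
        x = np.zeros(n)
    if gamma_hz is not None and gamma_amp > 0:
        t = np.arange(n) / fs_hz
        x = x + gamma_amp * np.sin(2 * np.pi * gamma_hz * t)
    return x
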