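"""Synthetic oddball EEG, flight sessions and pilot behavior with ground truth.

This module fabricates every input the pipeline consumes, under conditions
matching the emulated study: a 10-block x 60-tone three-class auditory
oddball (350 Hz standards 70-80%, 650 Hz targets 10-15%, 2000 Hz non-target
deviants 10-15%; 339 ms tones; 1.5 +/- 0.2 s onset asynchrony), 32-channel
500 Hz EEG with class-dependent ERP components riding on 1/f-plus-white
noise, a ~150 ms constant lag between marker and stimulus, and a scripted
flight scenario with stochastic pilot responses logged at 20 Hz.

Tones exist only as markers plus injected ERP waveforms; there is no audio,
no head-model forward simulation and no ocular/muscle artifact model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, EmptySessionError, ParameterError
from .prep import EEGRecording, MarkerStream
from .tracing import (
    INITIAL_COCKPIT_STATE,
    CockpitLog,
    ScenarioEvent,
)

__all__ = [
    "STANDARD",
    "TARGET",
    "DEVIANT",
    "FLIGHT_CODE_BASE",
    "CHANNELS_32",
    "ToneScheduleParams",
    "ERPComponent",
    "ERPTemplate",
    "NoiseSpec",
    "PilotProfile",
    "FlightEventTruth",
    "GroundTruth",
    "default_templates",
    "class_template_array",
    "generate_tone_schedule",
    "generate_oddball_eeg",
    "simulate_pilot_behavior",
    "build_cockpit_log",
    "simulate_flight_session",
]

STANDARD, TARGET, DEVIANT = 1, 2, 3
FLIGHT_CODE_BASE = 100

#: 32-channel actiCAP layout (10-20 names), reference FCz.
CHANNELS_32 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9", "CP5",
    "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "TP10", "CP6",
    "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "Fp2",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# tone schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneScheduleParams:
    """Oddball design parameters.

    Per-block class counts are drawn uniformly from the integer compositions
    admissible under ``p +/- halfwidth`` (defaults reproduce the 70-80% /
    10-15% / 10-15% ranges at 60 tones per block), so every block respects
    the stated proportion ranges while the long-run fractions converge to
    the nominal probabilities.
    """

    n_blocks: int = 10
    tones_per_block: int = 60
    p_standard: float = 0.75
    p_target: float = 0.125
    p_deviant: float = 0.125
    halfwidth_standard: float = 0.05
    halfwidth_rare: float = 0.025
    freq_standard_hz: float = 350.0
    freq_target_hz: float = 650.0
    freq_deviant_hz: float = 2000.0
    soa_mean_s: float = 1.5
    soa_jitter_s: float = 0.2
    tone_duration_s: float = 0.339
    marker_lag_s: float = 0.150
    block_break_s: float = 6.0
    lead_in_s: float = 2.0

    def __post_init__(self) -> None:
        probs = (self.p_standard, self.p_target, self.p_deviant)
        if any(not (0.0 <= p <= 1.0) for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterError("class probabilities must lie in [0,1] and sum to 1")
        if not (0.0 <= self.soa_jitter_s < self.soa_mean_s):
            raise ParameterError("soa_jitter_s must be non-negative and < soa_mean_s")
        if min(self.tone_duration_s, self.soa_mean_s) <= 0:
            raise ParameterError("durations must be positive")
        if self.n_blocks < 1 or self.tones_per_block < 1:
            raise ParameterError("need at least one block and one tone per block")

    @classmethod
    def from_dict(cls, d: dict) -> "ToneScheduleParams":
        return cls(**d)

    def _admissible_compositions(self) -> list[tuple[int, int, int]]:
        n = self.tones_per_block

        def bounds(p: float, hw: float) -> tuple[int, int]:
            lo = math.ceil((p - hw) * n - 1e-9)
            hi = math.floor((p + hw) * n + 1e-9)
            return max(lo, 0), min(hi, n)

        lo_s, hi_s = bounds(self.p_standard, self.halfwidth_standard)
        lo_t, hi_t = bounds(self.p_target, self.halfwidth_rare)
        lo_d, hi_d = bounds(self.p_deviant, self.halfwidth_rare)
        comps = [
            (n - t - d, t, d)
            for t in range(lo_t, hi_t + 1)
            for d in range(lo_d, hi_d + 1)
            if lo_s <= n - t - d <= hi_s
        ]
        if not comps:
            # Ranges too narrow for integer counts: fall back to the rounded
            # nominal composition.
            t = round(self.p_target * n)
            d = round(self.p_deviant * n)
            comps = [(n - t - d, t, d)]
        return comps


def generate_tone_schedule(params: ToneScheduleParams, seed) -> MarkerStream:
    """Draw a full oddball marker schedule.

    Onset gaps are uniform in ``soa_mean +/- soa_jitter``; blocks are
    separated by a fixed break. Identical seeds give identical schedules.
    """
    rng = _rng(seed)
    comps = params._admissible_compositions()
    times, codes = [], []
    t = params.lead_in_s
    for b in range(params.n_blocks):
        n_s, n_t, n_d = comps[int(rng.integers(len(comps)))]
        labels = np.array([STANDARD] * n_s + [TARGET] * n_t + [DEVIANT] * n_d)
        rng.shuffle(labels)
        for lab in labels:
            gap = rng.uniform(
                params.soa_mean_s - params.soa_jitter_s,
                params.soa_mean_s + params.soa_jitter_s,
            )
            t += gap
            times.append(t)
            codes.append(int(lab))
        t += params.block_break_s
    return MarkerStream(np.asarray(times), np.asarray(codes, dtype=int))


# ---------------------------------------------------------------------------
# ERP templates and noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ERPComponent:
    """One Gaussian-envelope component: peak latency relative to the true
    stimulus onset (the generator adds the pipeline lag), peak amplitude in
    microvolts and Gaussian temporal sd, with per-channel topography weights
    in [-1, 1]."""

    peak_latency_s: float
    amplitude_uV: float
    width_s: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        if self.width_s <= 0:
            raise ParameterError("component width must be positive")
        if np.any(np.abs(topo) > 1.0 + 1e-12):
            raise ParameterError("topography weights must lie in [-1, 1]")
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class ERPTemplate:
    class_code: int
    components: tuple[ERPComponent, ...]

    def __post_init__(self) -> None:
        n_ch = {c.topography.size for c in self.components}
        if len(n_ch) > 1:
            raise ConfigurationError("all components must share one channel count")


@dataclass(frozen=True)
class NoiseSpec:
    """Background EEG model: white Gaussian sensor noise plus a 1/f^alpha
    ("pink") process per channel, each specified by its standard deviation in
    microvolts. The 1/f part is what survives band-pass filtering and trial
    averaging, so it controls single-trial difficulty."""

    white_sd_uV: float = 10.0
    pink_exponent: float = 1.0
    pink_sd_uV: float = 12.0

    def __post_init__(self) -> None:
        if self.white_sd_uV < 0 or self.pink_sd_uV < 0:
            raise ParameterError("noise standard deviations must be non-negative")


def _topo_from_weights(labels: list[str], weights: dict[str, float], default: float) -> np.ndarray:
    return np.array([weights.get(lab, default) for lab in labels])


_FRONTOCENTRAL = {
    "Fz": 1.0, "FC1": 0.9, "FC2": 0.9, "Cz": 0.85, "F3": 0.7, "F4": 0.7,
    "C3": 0.6, "C4": 0.6, "FC5": 0.5, "FC6": 0.5, "CP1": 0.45, "CP2": 0.45,
    "Pz": 0.4, "F7": 0.35, "F8": 0.35, "T7": 0.3, "T8": 0.3,
}
_PARIETAL = {
    "Pz": 1.0, "CP1": 0.85, "CP2": 0.85, "P3": 0.8, "P4": 0.8, "Cz": 0.6,
    "CP5": 0.55, "CP6": 0.55, "Oz": 0.45, "P7": 0.4, "P8": 0.4, "O1": 0.35,
    "O2": 0.35, "TP9": 0.25, "TP10": 0.25,
}


def default_templates(
    channel_labels: list[str] | None = None,
    n100_amplitude_uV: float = -5.0,
    p300_amplitude_uV: float = 8.0,
) -> list[ERPTemplate]:
    """Default class templates.

    All tone classes elicit an N100-like fronto-central negativity (~100 ms);
    only targets additionally elicit a P300-like parietal positivity
    (~350 ms, broader). Deviants share the standard morphology: they are rare
    but task-irrelevant, and the binary decoder never sees them.
    """
    labels = channel_labels or CHANNELS_32
    n100 = ERPComponent(
        0.100, n100_amplitude_uV, 0.030, _topo_from_weights(labels, _FRONTOCENTRAL, 0.2)
    )
    p300 = ERPComponent(
        0.350, p300_amplitude_uV, 0.080, _topo_from_weights(labels, _PARIETAL, 0.15)
    )
    return [
        ERPTemplate(STANDARD, (n100,)),
        ERPTemplate(TARGET, (n100, p300)),
        ERPTemplate(DEVIANT, (n100,)),
    ]


def class_template_array(
    template: ERPTemplate, fs_hz: float, lag_s: float, duration_s: float
) -> np.ndarray:
    """Render a template as a channels x samples array over ``[0, duration)``
    relative to the *marker* time (component peaks appear at lag + latency)."""
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    out = np.zeros((template.components[0].topography.size, n))
    for comp in template.components:
        wave = comp.amplitude_uV * np.exp(
            -0.5 * ((t - (lag_s + comp.peak_latency_s)) / comp.width_s) ** 2
        )
        out += comp.topography[:, None] * wave[None, :]
    return out


def _background_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs_hz: float, noise: NoiseSpec
) -> np.ndarray:
    data = np.zeros((n_channels, n_samples))
    if noise.white_sd_uV > 0:
        data += rng.normal(0.0, noise.white_sd_uV, size=(n_channels, n_samples))
    if noise.pink_sd_uV > 0:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-noise.pink_exponent / 2.0)
        spec = (
            rng.normal(size=(n_channels, freqs.size))
            + 1j * rng.normal(size=(n_channels, freqs.size))
        ) * shape[None, :]
        pink = np.fft.irfft(spec, n=n_samples, axis=1)
        sd = pink.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data += pink * (noise.pink_sd_uV / sd)
    return data


def generate_oddball_eeg(
    schedule: MarkerStream,
    templates: list[ERPTemplate] | None = None,
    noise_spec: NoiseSpec | tuple = NoiseSpec(),
    n_channels: int = 32,
    fs_hz: float = 500.0,
    seed=0,
    marker_lag_s: float = 0.150,
    template_duration_s: float = 0.8,
    tail_s: float = 2.0,
    channel_labels: list[str] | None = None,
) -> tuple[EEGRecording, "GroundTruth"]:
    """Synthesize a continuous oddball recording.

    Every tone adds its class template (shifted by the pipeline lag) to the
    noise background; markers are stored at the nominal (unlagged) onsets,
    exactly as a trigger cable would record them.
    """
    if not isinstance(noise_spec, NoiseSpec):
        noise_spec = NoiseSpec(*noise_spec)
    labels = channel_labels or (CHANNELS_32 if n_channels == 32 else
                                [f"ch{i:02d}" for i in range(n_channels)])
    if len(labels) != n_channels:
        raise ConfigurationError("channel label count must equal n_channels")
    templates = templates if templates is not None else default_templates(labels)
    tmap = {t.class_code: t for t in templates}
    missing = sorted(set(schedule.codes.tolist()) - set(tmap))
    if missing:
        raise ConfigurationError(f"no ERP template for marker codes {missing}")

    rng = _rng(seed)
    n_samples = int(round((schedule.times[-1] + marker_lag_s + template_duration_s + tail_s) * fs_hz))
    data = _background_noise(rng, n_channels, n_samples, fs_hz, noise_spec)

    rendered = {
        code: class_template_array(tpl, fs_hz, marker_lag_s, marker_lag_s + template_duration_s)
        for code, tpl in tmap.items()
    }
    for t, code in zip(schedule.times, schedule.codes):
        s0 = int(round(t * fs_hz))
        wave = rendered[int(code)]
        data[:, s0 : s0 + wave.shape[1]] += wave

    rec = EEGRecording(data, fs_hz, list(labels), schedule)
    truth = GroundTruth(tone_labels=schedule.codes.copy())
    return rec, truth


# ---------------------------------------------------------------------------
# pilot behavior and flight sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PilotProfile:
    """Stochastic stand-in for a pilot's response behavior.

    Per analyzable event the pilot omits with probability ``p_omission``,
    commits a wrong entry with ``p_commission``, and otherwise responds
    adequately. Response latencies are log-normal (positive, right-skewed
    reaction times) with the given median and log-sd, resampled into the
    response window. The attended flag ties behavior to the EEG ground
    truth: adequate responders attended with ``p_attend_adequate``; lapsing
    pilots attended with ``p_attend_lapse`` (an attended lapse is behavior
    the relevance gate cannot and should not explain away).
    """

    p_omission: float = 0.14
    p_commission: float = 0.14
    latency_median_s: float = 8.0
    latency_spread: float = 0.5
    p_attend_adequate: float = 1.0
    p_attend_lapse: float = 0.5
    p_attend_unanalyzed: float = 0.7

    def __post_init__(self) -> None:
        if self.p_omission < 0 or self.p_commission < 0:
            raise ParameterError("error probabilities must be non-negative")
        if self.p_omission + self.p_commission > 1.0 + 1e-12:
            raise ParameterError("p_omission + p_commission must not exceed 1")
        if self.latency_median_s <= 0 or self.latency_spread < 0:
            raise ParameterError("latency parameters must be positive")


@dataclass(frozen=True)
class FlightEventTruth:
    event_id: str
    attended: bool
    category: str | None = None  # None for events without an adequacy rule
    latency_s: float | None = None


@dataclass
class GroundTruth:
    """Per-session ground truth emitted alongside every generated input."""

    tone_labels: np.ndarray | None = None
    flight_events: list[FlightEventTruth] = field(default_factory=list)
    marker_event_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tone_labels": None
            if self.tone_labels is None
            else np.asarray(self.tone_labels).tolist(),
            "flight_events": [asdict(fe) for fe in self.flight_events],
            "marker_event_ids": list(self.marker_event_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            tone_labels=None if d["tone_labels"] is None else np.asarray(d["tone_labels"]),
            flight_events=[FlightEventTruth(**fe) for fe in d["flight_events"]],
            marker_event_ids=list(d["marker_event_ids"]),
        )


def _draw_latency(rng: np.random.Generator, profile: PilotProfile, limit_s: float) -> float:
    # log-normal, resampled into (0.2, limit]; mass beyond the limit is
    # negligible at the defaults so resampling barely distorts the shape
    for _ in range(1000):
        lat = float(
            np.exp(rng.normal(np.log(profile.latency_median_s), profile.latency_spread))
        )
        if 0.2 <= lat <= limit_s:
            return lat
    return min(max(profile.latency_median_s, 0.2), limit_s)


def simulate_pilot_behavior(
    events: list[ScenarioEvent], profile: PilotProfile, seed
) -> list[FlightEventTruth]:
    """Draw one pilot's responses and attention flags for a scenario."""
    rng = _rng(seed)
    truth = []
    for ev in events:
        if not ev.has_marker and not ev.analyzable:
            continue
        if ev.analyzable:
            u = rng.random()
            if u < profile.p_omission:
                cat, lat = "omission", None
            elif u < profile.p_omission + profile.p_commission:
                cat, lat = "commission", _draw_latency(rng, profile, ev.response_limit_s)
            else:
                cat, lat = "adequate", _draw_latency(rng, profile, ev.response_limit_s)
            p_att = profile.p_attend_adequate if cat == "adequate" else profile.p_attend_lapse
            attended = bool(rng.random() < p_att)
        else:
            cat, lat = None, None
            attended = bool(rng.random() < profile.p_attend_unanalyzed)
        truth.append(FlightEventTruth(ev.event_id, attended, cat, lat))
    return truth


def build_cockpit_log(
    events: list[ScenarioEvent],
    truth: list[FlightEventTruth],
    rate_hz: float = 20.0,
    duration_s: float | None = None,
    initial_state: dict[str, float] | None = None,
) -> tuple[CockpitLog, list[FlightEventTruth]]:
    """Write the 20 Hz parameter log implied by the simulated behavior.

    Adequate responses step every required parameter to its target at
    onset + latency (multiple parameters staggered by 1 s); commissions step
    the first required parameter to a wrong value; omissions write nothing,
    so the ground-truth invariant "omission => no qualifying change" holds
    by construction.

    Returns the log together with the *effective* ground truth: when a
    lapsed earlier event leaves a parameter already sitting at a later
    event's target, an adequate re-entry of the same value is invisible in a
    sampled state log, and the event is demoted to an omission — the tracer
    can only ever read what the log shows.
    """
    state = dict(initial_state or INITIAL_COCKPIT_STATE)
    for ev in events:
        for p, _ in ev.required_changes:
            state.setdefault(p, 0.0)
    if duration_s is None:
        duration_s = max(e.onset_s + e.response_limit_s for e in events) + 10.0
    n = int(round(duration_s * rate_hz)) + 1
    times = np.arange(n) / rate_hz
    params = {p: np.full(n, v, dtype=float) for p, v in state.items()}

    tmap = {t.event_id: t for t in truth}
    ops: list[tuple[float, str, object, str]] = []  # (time, param, value, event_id)
    for ev in sorted(events, key=lambda e: e.onset_s):
        if not ev.analyzable or ev.event_id not in tmap:
            continue
        fe = tmap[ev.event_id]
        if fe.category == "adequate":
            for k, (p, v) in enumerate(ev.required_changes):
                t_change = min(ev.onset_s + fe.latency_s + k * 1.0,
                               ev.onset_s + ev.response_limit_s)
                ops.append((t_change, p, v, ev.event_id))
        elif fe.category == "commission":
            p, v = ev.required_changes[0]
            ops.append((ev.onset_s + fe.latency_s, p, ("WRONG", v), ev.event_id))

    current = dict(state)
    invisible: set[str] = set()
    for t_change, p, v, eid in sorted(ops, key=lambda o: o[0]):
        if isinstance(v, tuple):  # commission: any value that is a visible, wrong change
            target = v[1]
            wrong = target - 20.0
            if wrong == current[p] or wrong == target:
                wrong = target + 20.0
            v = wrong
        elif v == current[p]:  # adequate re-entry of the standing value: no visible change
            invisible.add(eid)
            continue
        idx = int(np.searchsorted(times, t_change, side="left"))
        if idx < n:
            params[p][idx:] = v
            current[p] = v
    truth_out = [
        FlightEventTruth(fe.event_id, fe.attended, "omission", None)
        if fe.event_id in invisible
        else fe
        for fe in truth
    ]
    return CockpitLog(times, params), truth_out


def simulate_flight_session(
    events: list[ScenarioEvent],
    profile: PilotProfile,
    templates: list[ERPTemplate] | None = None,
    seed=0,
    fs_hz: float = 500.0,
    n_channels: int = 32,
    noise_spec: NoiseSpec | tuple = NoiseSpec(),
    marker_lag_s: float = 0.150,
    log_rate_hz: float = 20.0,
    channel_labels: list[str] | None = None,
) -> tuple[EEGRecording, CockpitLog, GroundTruth]:
    """Simulate one pilot's full flight session.

    Each marker-bearing scenario event contributes one EEG marker
    (code = 100 + running index); attended events carry the target-class ERP,
    unattended ones the standard-class ERP. The cockpit log reflects the
    drawn response categories.
    """
    if not events:
        raise EmptySessionError("scenario contains no events")
    if not isinstance(noise_spec, NoiseSpec):
        noise_spec = NoiseSpec(*noise_spec)
    labels = channel_labels or (CHANNELS_32 if n_channels == 32 else
                                [f"ch{i:02d}" for i in range(n_channels)])
    templates = templates if templates is not None else default_templates(labels)
    tmap = {t.class_code: t for t in templates}
    if STANDARD not in tmap or TARGET not in tmap:
        raise ConfigurationError("flight simulation needs standard and target templates")

    rng = _rng(seed)
    truth_list = simulate_pilot_behavior(events, profile, rng)
    log, truth_list = build_cockpit_log(events, truth_list, rate_hz=log_rate_hz)

    marker_events = [e for e in sorted(events, key=lambda e: e.onset_s) if e.has_marker]
    attended = {fe.event_id: fe.attended for fe in truth_list}
    times = np.array([e.onset_s for e in marker_events])
    codes = np.array([FLIGHT_CODE_BASE + i for i in range(len(marker_events))], dtype=int)
    markers = MarkerStream(times, codes)

    duration = float(times[-1]) + 30.0
    n_samples = int(round(duration * fs_hz))
    data = _background_noise(rng, n_channels, n_samples, fs_hz, noise_spec)

    rendered = {
        code: class_template_array(tmap[code], fs_hz, marker_lag_s, marker_lag_s + 0.8)
        for code in (STANDARD, TARGET)
    }
    for ev in marker_events:
        s0 = int(round(ev.onset_s * fs_hz))
        wave = rendered[TARGET if attended.get(ev.event_id, False) else STANDARD]
        data[:, s0 : s0 + wave.shape[1]] += wave

    rec = EEGRecording(data, fs_hz, list(labels), markers)
    truth = GroundTruth(
        flight_events=truth_list,
        marker_event_ids=[e.event_id for e in marker_events],
    )
    return rec, log, truth
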