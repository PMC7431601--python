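"""Flight scenario encoding and model tracing of pilot responses.

A scripted single-pilot scenario (ATC instructions, cautions, a warning)
defines, per event, the normative flight-deck response: a set of parameter
changes that must appear in the 20 Hz cockpit log within a response window
(25 s by default). Two tracers classify observed behavior event by event:

* the **normative** tracer scores an event as correctly classified iff the
  response was adequate (right parameters, right values, in time);
* the **neuroadaptive** tracer additionally consults a single-trial EEG
  relevance score per event: a non-adequate response to an event whose
  auditory onset was decoded as *not* processed as task-relevant
  (score < 1.5) is scored as correctly classified — the operator plausibly
  never attended the alert, so the absent response is explained rather than
  unexplained.

The gate can only convert incorrect classifications into correct ones, so
neuroadaptive accuracy dominates normative accuracy by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, EmptySessionError, ParameterError

__all__ = [
    "ScenarioEvent",
    "CockpitLog",
    "ResponseAssessment",
    "TraceOutcome",
    "ProcedureStep",
    "default_scenario",
    "load_scenario",
    "scenario_to_dicts",
    "assess_response",
    "trace_normative",
    "trace_neuroadaptive",
    "emulate_alert_procedure",
    "RELEVANCE_GATE",
]

#: Relevance-score boundary: scores below this mean "processed as irrelevant".
RELEVANCE_GATE = 1.5

_EVENT_KINDS = {"ATC", "caution", "warning", "spurious", "silent"}


@dataclass(frozen=True)
class ScenarioEvent:
    """One scripted event with its adequacy rule.

    ``required_changes`` is a tuple of (parameter, target value) pairs that an
    adequate response must produce within ``response_limit_s`` of onset;
    spurious and purely informational events carry an empty tuple.
    ``analysis_included`` marks the events entering accuracy denominators.
    ``reconstructed`` flags schedule details not scripted in the source
    scenario but required to complete it.
    """

    event_id: str
    kind: str
    onset_s: float
    required_changes: tuple[tuple[str, float], ...] = ()
    response_limit_s: float = 25.0
    analysis_included: bool = True
    has_marker: bool = True
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.onset_s < 0:
            raise ConfigurationError("event onset must be >= 0")
        if self.kind == "spurious" and self.required_changes:
            raise ConfigurationError("spurious events cannot require a parameter change")
        if self.analysis_included and self.kind in {"ATC", "caution", "warning"}:
            if not self.required_changes:
                raise ConfigurationError(
                    f"analyzable {self.kind} event {self.event_id!r} needs an adequacy rule"
                )

    @property
    def analyzable(self) -> bool:
        return self.analysis_included and bool(self.required_changes)


@dataclass
class CockpitLog:
    """Uniformly sampled cockpit system state (default 20 Hz).

    ``params`` maps parameter names (altitude_select, speed_select, ...) to
    sample arrays aligned with ``times_s``.
    """

    times_s: np.ndarray
    params: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.size < 2:
            raise ParameterError("cockpit log needs at least two samples")
        dt = np.diff(self.times_s)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("cockpit log timestamps must be strictly increasing and uniform")
        for name, arr in self.params.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times_s.shape:
                raise ParameterError(f"parameter channel {name!r} misaligned with timestamps")
            self.params[name] = arr

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.times_s, **self.params})
        df.to_csv(path, index=False, float_format="%.3f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CockpitLog":
        df = pd.read_csv(path)
        times = df.pop("time_s").to_numpy(float)
        return cls(times, {c: df[c].to_numpy(float) for c in df.columns})


@dataclass(frozen=True)
class ResponseAssessment:
    """Category of the observed response to one event."""

    event_id: str
    category: str  # adequate | commission | omission
    latency_s: float | None = None
    observed: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.category not in {"adequate", "commission", "omission"}:
            raise ParameterError(f"unknown response category {self.category!r}")
        if self.category == "omission" and self.latency_s is not None:
            raise ParameterError("omission carries no latency")


@dataclass(frozen=True)
class TraceOutcome:
    event_id: str
    model: str  # normative | neuroadaptive
    classification_correct: bool
    reason: str  # adequate-response | gated-irrelevant | unexplained-omission | unexplained-commission


@dataclass(frozen=True)
class ProcedureStep:
    """One module event in the emulated alert-processing procedure."""

    t_s: float
    module: str
    phase: str
    detail: str | None = None


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

def default_scenario() -> list[ScenarioEvent]:
    """The shipped flight scenario.

    Eight ATC instructions, a fuel-pump caution at 4 min, a silent fuel leak
    at 6 min, a TCAS traffic advisory near 7 min, four spurious electrical
    cautions, a fuel-imbalance caution excluded from analysis, and an
    engine-fire warning at 16:40. ATC onsets are not part of the scripted
    timeline; they are spread evenly between the scripted alerts and the
    eighth ATC slot is a reconstruction.
    """
    ev = ScenarioEvent
    return [
        ev("atc1", "ATC", 60.0, (("altitude_select", 280.0), ("speed_select", 220.0))),
        ev("atc2", "ATC", 150.0, (("altitude_select", 300.0),)),
        ev("fuel_pump", "caution", 240.0, (("right_main_pump", 0.0),)),
        ev("elec1", "spurious", 300.0, analysis_included=False),
        ev("atc3", "ATC", 330.0, (("altitude_select", 280.0),)),
        ev("fuel_leak", "silent", 360.0, analysis_included=False, has_marker=False),
        ev("tcas_ta", "caution", 420.0, analysis_included=False),
        ev("atc4", "ATC", 450.0, (("altitude_select", 300.0),)),
        ev("elec2", "spurious", 510.0, analysis_included=False),
        ev("atc5", "ATC", 560.0, (("altitude_select", 320.0),)),
        ev("atc6", "ATC", 640.0, (("heading_select", 325.0),)),
        ev("elec3", "spurious", 700.0, analysis_included=False),
        ev("fuel_imbalance", "caution", 760.0, (("fuel_x_feed", 1.0),), analysis_included=False),
        ev("atc7", "ATC", 820.0, (("heading_select", 350.0),)),
        ev("elec4", "spurious", 880.0, analysis_included=False),
        ev("atc8", "ATC", 930.0, (("speed_select", 240.0),), reconstructed=True),
        ev("engine_fire", "warning", 1000.0, (("fire_extinguish", 1.0),)),
    ]


#: Parameter values at scenario start (cruise at FL 250, pumps on).
INITIAL_COCKPIT_STATE: dict[str, float] = {
    "altitude_select": 250.0,
    "speed_select": 250.0,
    "heading_select": 90.0,
    "right_main_pump": 1.0,
    "fuel_x_feed": 0.0,
    "fire_extinguish": 0.0,
}


def scenario_to_dicts(events: list[ScenarioEvent]) -> list[dict]:
    return [
        {
            "event_id": e.event_id,
            "kind": e.kind,
            "onset_s": e.onset_s,
            "required_changes": [[p, v] for p, v in e.required_changes],
            "response_limit_s": e.response_limit_s,
            "analysis_included": e.analysis_included,
            "has_marker": e.has_marker,
            "reconstructed": e.reconstructed,
        }
        for e in events
    ]


def load_scenario(source: str | Path | list | dict) -> list[ScenarioEvent]:
    """Load a scenario from YAML/JSON (path) or an already-parsed structure.

    Accepts either a bare list of event mappings or ``{"events": [...]}``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        raw = source
    if isinstance(raw, dict):
        raw = raw.get("events", [])
    if not raw:
        raise EmptySessionError("scenario contains no events")
    events = []
    for item in raw:
        events.append(
            ScenarioEvent(
                event_id=str(item["event_id"]),
                kind=str(item["kind"]),
                onset_s=float(item["onset_s"]),
                required_changes=tuple(
                    (str(p), float(v)) for p, v in item.get("required_changes", [])
                ),
                response_limit_s=float(item.get("response_limit_s", 25.0)),
                analysis_included=bool(item.get("analysis_included", True)),
                has_marker=bool(item.get("has_marker", True)),
                reconstructed=bool(item.get("reconstructed", False)),
            )
        )
    if len({e.event_id for e in events}) != len(events):
        raise ConfigurationError("duplicate event ids in scenario")
    return events


# ---------------------------------------------------------------------------
# response assessment
# ---------------------------------------------------------------------------

def assess_response(
    event: ScenarioEvent,
    log: CockpitLog,
    value_tol: float = 0.0,
    inclusive_limit: bool = True,
) -> ResponseAssessment:
    """Scan the cockpit log for the first reaction to ``event``.

    For each required parameter, the scan window is ``(onset, onset + limit]``
    (boundary inclusive by default) and the baseline is the logged value at
    onset. The *first* change of a required parameter decides its verdict: a
    change to the target value (within ``value_tol``) is adequate for that
    parameter, any other first value is a commission — a later correction
    inside the window does not rescue it. A parameter that never changes
    within the window (including changes that come too late) is an omission.

    Event verdict: any commission among the required parameters ⇒ commission;
    otherwise any missing change ⇒ omission; otherwise adequate, with latency
    the time by which all required changes were in place.
    """
    if not event.required_changes:
        raise ConfigurationError(f"event {event.event_id!r} has no adequacy rule to assess")
    t = log.times_s
    onset, limit = event.onset_s, event.response_limit_s
    if t[0] > onset or t[-1] < onset + limit:
        raise ConfigurationError(
            f"log does not cover the response window of event {event.event_id!r}"
        )

    per_param: list[tuple[str, str, float | None, float | None]] = []
    for param, target in event.required_changes:
        if param not in log.params:
            raise ConfigurationError(f"parameter channel {param!r} missing from log")
        series = log.params[param]
        base_idx = int(np.searchsorted(t, onset, side="right")) - 1
        baseline = series[base_idx]
        if inclusive_limit:
            window = (t > onset) & (t <= onset + limit)
        else:
            window = (t > onset) & (t < onset + limit)
        idx = np.flatnonzero(window & (series != baseline))
        if idx.size == 0:
            per_param.append((param, "omission", None, None))
            continue
        first = idx[0]
        value = float(series[first])
        latency = float(t[first] - onset)
        verdict = "adequate" if abs(value - target) <= value_tol else "commission"
        per_param.append((param, verdict, latency, value))

    observed = tuple((p, v) for p, cat, lat, v in per_param if v is not None)
    commissions = [x for x in per_param if x[1] == "commission"]
    if commissions:
        return ResponseAssessment(
            event.event_id, "commission", latency_s=commissions[0][2], observed=observed
        )
    if any(x[1] == "omission" for x in per_param):
        return ResponseAssessment(event.event_id, "omission", observed=observed)
    latency = max(x[2] for x in per_param)
    return ResponseAssessment(event.event_id, "adequate", latency_s=latency, observed=observed)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def _analyzable(events: list[ScenarioEvent]) -> list[ScenarioEvent]:
    return [e for e in events if e.analyzable]


def trace_normative(
    events: list[ScenarioEvent], assessments: dict[str, ResponseAssessment] | list[ResponseAssessment]
) -> tuple[list[TraceOutcome], float]:
    """Normative tracing: correct classification iff the response was adequate."""
    amap = _as_map(assessments)
    outcomes = []
    for e in _analyzable(events):
        cat = amap[e.event_id].category
        correct = cat == "adequate"
        reason = "adequate-response" if correct else f"unexplained-{cat}"
        outcomes.append(TraceOutcome(e.event_id, "normative", correct, reason))
    if not outcomes:
        raise EmptySessionError("no analyzable events to trace")
    acc = sum(o.classification_correct for o in outcomes) / len(outcomes)
    return outcomes, acc


def trace_neuroadaptive(
    events: list[ScenarioEvent],
    assessments: dict[str, ResponseAssessment] | list[ResponseAssessment],
    scores: dict[str, float],
) -> tuple[list[TraceOutcome], float]:
    """Neuroadaptive tracing: the relevance gate explains away non-responses.

    A non-adequate response whose event was decoded as processed-as-irrelevant
    (score < 1.5) is scored as a correct behavior classification; exactly 1.5
    counts as relevant (the strict <1.5 irrelevance rule).
    """
    amap = _as_map(assessments)
    outcomes = []
    for e in _analyzable(events):
        if e.event_id not in scores:
            raise ParameterError(f"missing relevance score for analyzable event {e.event_id!r}")
        cat = amap[e.event_id].category
        if cat == "adequate":
            outcomes.append(TraceOutcome(e.event_id, "neuroadaptive", True, "adequate-response"))
        elif scores[e.event_id] < RELEVANCE_GATE:
            outcomes.append(TraceOutcome(e.event_id, "neuroadaptive", True, "gated-irrelevant"))
        else:
            outcomes.append(
                TraceOutcome(e.event_id, "neuroadaptive", False, f"unexplained-{cat}")
            )
    if not outcomes:
        raise EmptySessionError("no analyzable events to trace")
    acc = sum(o.classification_correct for o in outcomes) / len(outcomes)
    return outcomes, acc


def _as_map(
    assessments: dict[str, ResponseAssessment] | list[ResponseAssessment]
) -> dict[str, ResponseAssessment]:
    if isinstance(assessments, dict):
        return assessments
    return {a.event_id: a for a in assessments}


# ---------------------------------------------------------------------------
# alert-processing procedure
# ---------------------------------------------------------------------------

#: Nominal module latencies (s) for the deterministic alert-processing trace:
#: one production firing is 50 ms, a visual attention shift 85 ms, reading and
#: memory encoding a few hundred ms. The exact values only shape the trace
#: timeline; classification never depends on them.
_PHASE_OFFSETS = (
    ("aural", "aural-detect", 0.0),
    ("procedural", "decode-and-start-timer", 0.05),
    ("visual", "shift-attention-to-display", 0.135),
    ("visual", "read-message", 0.435),
    ("imaginal", "memorize-first-checklist-item", 0.635),
    ("motor", "execute-first-action", 0.935),
    ("procedural", "work-remaining-items", 1.135),
)


def emulate_alert_procedure(event: ScenarioEvent) -> list[ProcedureStep]:
    """Deterministic state-machine trace of alert processing for one event.

    Emits the fixed eight-phase sequence — sound detection, procedural decode
    with timer start, visual shift, message reading, checklist-item encoding,
    the first motor action, the remaining items, and a final verification —
    with the verification firing exactly when the internal count reaches the
    event's response limit. The verification step reads the same parameter
    that response assessment scans, tying the two modules to one rule.
    """
    first_param = event.required_changes[0][0] if event.required_changes else None
    steps = [
        ProcedureStep(event.onset_s + dt, module, phase, detail=None)
        for module, phase, dt in _PHASE_OFFSETS
    ]
    steps.append(
        ProcedureStep(
            event.onset_s + event.response_limit_s,
            "temporal",
            "verify-response",
            detail=first_param,
        )
    )
    return steps
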