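"""End-to-end study orchestration: generate -> prep -> train -> apply ->
trace -> report, reproducible from one integer seed.

``StudyModel(config).fit(seed)`` runs the whole emulated study for a cohort
of pilots and returns a ``StudyResults`` object wrapping the aggregate
statistics, per-pilot artifacts and provenance (config hash + seed). One
global seed is expanded into per-stage, per-pilot substreams through
``numpy`` seed sequences keyed on (stage, pilot), so enlarging the cohort
never reshuffles earlier pilots.

Three classifier modes:

* ``"eeg"`` — the full pipeline: per pilot, synthesize an oddball session,
  band-pass, epoch, train the shrinkage-LDA relevance decoder with
  chronological margin CV, then score that pilot's flight-event epochs.
* ``"surrogate"`` — skip EEG synthesis and emulate the decoder as a
  Bernoulli channel of configurable reliability on the attended/unattended
  ground truth. Useful for large cohort sweeps where only tracing and the
  statistics are under study.
* ``"none"`` — normative tracing only; neuroadaptive fields are null.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    CVConfig,
    FeatureConfig,
    cross_validate,
    extract_windowed_means,
    fit_shrinkage_lda,
    predict_relevance,
)
from .exceptions import ConfigurationError
from .prep import bandpass, cut_epochs
from .stats import PilotOutcome, StudyResult, build_study_report
from .synthetic import (
    STANDARD,
    TARGET,
    NoiseSpec,
    PilotProfile,
    ToneScheduleParams,
    build_cockpit_log,
    default_templates,
    generate_oddball_eeg,
    generate_tone_schedule,
    simulate_flight_session,
    simulate_pilot_behavior,
)
from .tracing import (
    ScenarioEvent,
    assess_response,
    default_scenario,
    load_scenario,
    scenario_to_dicts,
    trace_neuroadaptive,
    trace_normative,
)

__all__ = ["StudyConfig", "StudyModel", "StudyResults", "run_study", "derive_seed"]

_STAGE = {"schedule": 0, "oddball": 1, "flight": 2, "surrogate": 3}


def derive_seed(seed: int, stage: str, pilot: int) -> int:
    """Deterministic per-stage, per-pilot child seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE[stage], int(pilot)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    """Everything a study run depends on, apart from the seed."""

    n_pilots: int = 21
    classifier_mode: str = "eeg"  # eeg | surrogate | none
    surrogate_reliability: float = 0.88
    tone: ToneScheduleParams = field(default_factory=ToneScheduleParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_channels: int = 32
    fs_hz: float = 500.0
    band: tuple[float, float] = (0.3, 20.0)
    epoch_window: tuple[float, float] = (-0.2, 0.8)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    profile: PilotProfile = field(default_factory=PilotProfile)
    scenario: list[ScenarioEvent] | None = None  # None -> shipped default
    marker_lag_s: float = 0.150
    shrinkage: float | str = "auto"
    n100_amplitude_uV: float = -5.0
    p300_amplitude_uV: float = 8.0
    classifier_accuracy_override: float | None = None

    def __post_init__(self) -> None:
        if self.classifier_mode not in {"eeg", "surrogate", "none"}:
            raise ConfigurationError(f"unknown classifier mode {self.classifier_mode!r}")
        if self.n_pilots < 1:
            raise ConfigurationError("need at least one pilot")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "tone" in d:
            d["tone"] = ToneScheduleParams(**d["tone"])
        if "noise" in d:
            d["noise"] = NoiseSpec(**d["noise"])
        if "feature" in d:
            d["feature"] = FeatureConfig(**d["feature"])
        if "cv" in d:
            d["cv"] = CVConfig(**d["cv"])
        if "profile" in d:
            d["profile"] = PilotProfile(**d["profile"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        if d.get("scenario") is not None:
            d["scenario"] = load_scenario(d["scenario"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def events(self) -> list[ScenarioEvent]:
        return self.scenario if self.scenario is not None else default_scenario()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = None if self.scenario is None else scenario_to_dicts(self.scenario)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StudyModel:
    """Full-pipeline study model; ``fit(seed)`` executes it."""

    def __init__(self, config: StudyConfig | None = None):
        self.config = config or StudyConfig()

    # -- single-pilot stages -------------------------------------------------

    def _train_decoder(self, pilot: int, seed: int):
        cfg = self.config
        schedule = generate_tone_schedule(cfg.tone, derive_seed(seed, "schedule", pilot))
        templates = self._templates()
        rec, _truth = generate_oddball_eeg(
            schedule,
            templates,
            cfg.noise,
            n_channels=cfg.n_channels,
            fs_hz=cfg.fs_hz,
            seed=derive_seed(seed, "oddball", pilot),
            marker_lag_s=cfg.marker_lag_s,
        )
        filt = bandpass(rec, *cfg.band)
        epochs = cut_epochs(filt, cfg.epoch_window, label_map={STANDARD: 0, TARGET: 1})
        X = extract_windowed_means(epochs, cfg.feature)
        y = epochs.labels.astype(int)
        cv_res = cross_validate(X, y, cfg.cv, shrinkage=cfg.shrinkage)
        model = fit_shrinkage_lda(X, y, cfg.shrinkage)
        model.feature_config = cfg.feature
        model.channel_labels = epochs.channel_labels
        return model, cv_res

    def _templates(self):
        cfg = self.config
        labels = None if cfg.n_channels == 32 else [f"ch{i:02d}" for i in range(cfg.n_channels)]
        return default_templates(
            channel_labels=labels,
            n100_amplitude_uV=cfg.n100_amplitude_uV,
            p300_amplitude_uV=cfg.p300_amplitude_uV,
        )

    def _run_pilot(self, pilot: int, seed: int) -> PilotOutcome:
        cfg = self.config
        events = self.config.events()
        analyzable = [e for e in events if e.analyzable]

        if cfg.classifier_mode == "eeg":
            model, cv_res = self._train_decoder(pilot, seed)
            rec, log, truth = simulate_flight_session(
                events,
                cfg.profile,
                self._templates(),
                seed=derive_seed(seed, "flight", pilot),
                fs_hz=cfg.fs_hz,
                n_channels=cfg.n_channels,
                noise_spec=cfg.noise,
                marker_lag_s=cfg.marker_lag_s,
            )
            filt = bandpass(rec, *cfg.band)
            epochs = cut_epochs(filt, cfg.epoch_window)
            scores_all = predict_relevance(model, epochs, event_ids=truth.marker_event_ids)
            scores = {s.event_id: s.value for s in scores_all}
            cv_acc = cv_res.mean_accuracy
        else:
            truth_list = simulate_pilot_behavior(
                events, cfg.profile, derive_seed(seed, "flight", pilot)
            )
            log, truth_list = build_cockpit_log(events, truth_list)
            cv_acc = None
            if cfg.classifier_mode == "surrogate":
                rng = np.random.default_rng(derive_seed(seed, "surrogate", pilot))
                attended = {fe.event_id: fe.attended for fe in truth_list}
                scores = {}
                for e in analyzable:
                    decode_ok = rng.random() < cfg.surrogate_reliability
                    relevant = attended[e.event_id] if decode_ok else not attended[e.event_id]
                    scores[e.event_id] = 1.75 if relevant else 1.25
            else:
                scores = None

        assessments = {e.event_id: assess_response(e, log) for e in analyzable}
        norm_outcomes, _ = trace_normative(events, assessments)
        neuro_outcomes = None
        if scores is not None:
            neuro_outcomes, _ = trace_neuroadaptive(events, assessments, scores)
        return PilotOutcome(
            pilot_id=pilot,
            normative=norm_outcomes,
            neuroadaptive=neuro_outcomes,
            scores=scores,
            categories={eid: a.category for eid, a in assessments.items()},
            cv_accuracy=cv_acc,
        )

    # -- cohort --------------------------------------------------------------

    def fit(self, seed: int = 0) -> "StudyResults":
        cfg = self.config
        pilots = [self._run_pilot(i, seed) for i in range(cfg.n_pilots)]
        if cfg.classifier_accuracy_override is not None:
            clf_acc = cfg.classifier_accuracy_override
        elif cfg.classifier_mode == "eeg":
            clf_acc = float(np.mean([p.cv_accuracy for p in pilots]))
        elif cfg.classifier_mode == "surrogate":
            clf_acc = cfg.surrogate_reliability
        else:
            clf_acc = None
        study = build_study_report(pilots, classifier_accuracy=clf_acc)
        # latencies for the events table
        return StudyResults(study=study, pilots=pilots, config=cfg, seed=seed)


@dataclass
class StudyResults:
    """Fitted study: aggregate statistics plus per-pilot artifacts."""

    study: StudyResult
    pilots: list[PilotOutcome]
    config: StudyConfig
    seed: int

    def summary(self) -> str:
        head = (
            f"seed {self.seed}   config {self.config.config_hash()}   "
            f"classifier mode: {self.config.classifier_mode}\n"
        )
        return head + self.study.summary()

    def events_frame(self) -> pd.DataFrame:
        """One row per analyzable event per pilot."""
        rows = []
        for p in self.pilots:
            neuro = {o.event_id: o for o in (p.neuroadaptive or [])}
            for o in p.normative:
                n = neuro.get(o.event_id)
                rows.append(
                    {
                        "pilot": p.pilot_id,
                        "event_id": o.event_id,
                        "category": p.categories.get(o.event_id),
                        "score": None if p.scores is None else p.scores.get(o.event_id),
                        "normative_correct": o.classification_correct,
                        "normative_reason": o.reason,
                        "neuroadaptive_correct": None if n is None else n.classification_correct,
                        "neuroadaptive_reason": None if n is None else n.reason,
                    }
                )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "study": self.study.to_json_dict(),
        }

    def save(self, out_dir: str | Path) -> None:
        """Write study_report.json, per_pilot.tsv and events.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(
            json.dumps(self.to_json_dict(), sort_keys=True, indent=1, default=str)
        )
        self.study.per_pilot.to_csv(out / "per_pilot.tsv", sep="\t", index=False)
        self.events_frame().to_csv(out / "events.tsv", sep="\t", index=False)


def run_study(
    config: StudyConfig | None = None, seed: int = 0, out_dir: str | Path | None = None
) -> StudyResults:
    """Convenience wrapper: fit a study and optionally save its reports."""
    results = StudyModel(config).fit(seed)
    if out_dir is not None:
        results.save(out_dir)
    return results
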