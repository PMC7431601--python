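"""Uncertainty decomposition, comparison statistics and study aggregation.

Model tracing carries two distinct kinds of uncertainty. *Epistemic*
uncertainty is the fraction of behavior a tracer cannot explain (one minus
its accuracy) — reducible by feeding the model more information, which is
exactly what the relevance gate does. *Aleatory* uncertainty is the
irreducible error inherited from the EEG classifier: of the accuracy the
gate adds, a share equal to one minus the classifier's accuracy rests on
unreliable evidence. The corrected neuroadaptive accuracy therefore scales
the added value by the classifier accuracy:

    added      = acc_neuro - acc_norm
    corrected  = acc_norm + acc_clf * added
    mu_alea    = (1 - acc_clf) * added
    mu_epi     = 1 - corrected

so that corrected + mu_epi = 1 and corrected = acc_norm + added - mu_alea
hold exactly. With the printed study inputs (0.72, 0.87, 0.88) this yields
0.85 / 0.15 / 0.02 at two decimals. The formula is a reconstruction from
those printed values; it is the unique affine correction consistent with
all three.

All computation is done in full precision; rounding to two decimals happens
only in report layers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, ParameterError
from .tracing import RELEVANCE_GATE, TraceOutcome

__all__ = [
    "UncertaintyReport",
    "StudyResult",
    "PilotOutcome",
    "decompose_uncertainty",
    "paired_t",
    "cohens_d_av",
    "chi_square_2x2",
    "build_study_report",
]


@dataclass(frozen=True)
class UncertaintyReport:
    """Accuracy of one tracer with its uncertainty decomposition."""

    model: str
    accuracy: float
    mu_epistemic: float
    mu_aleatory: float = 0.0
    corrected_accuracy: float | None = None
    classifier_accuracy: float | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        out = {
            "model": self.model,
            "accuracy": round(self.accuracy, ndigits),
            "mu_epistemic": round(self.mu_epistemic, ndigits),
            "mu_aleatory": round(self.mu_aleatory, ndigits),
        }
        if self.corrected_accuracy is not None:
            out["corrected_accuracy"] = round(self.corrected_accuracy, ndigits)
            out["classifier_accuracy"] = round(self.classifier_accuracy, ndigits)
        return out


def decompose_uncertainty(
    norm_acc: float, neuro_acc: float, clf_acc: float
) -> UncertaintyReport:
    """Correct the neuroadaptive accuracy for classifier unreliability.

    Raises if ``neuro_acc < norm_acc``: the relevance gate can only convert
    unexplained events into explained ones, so that ordering would indicate
    an upstream defect.
    """
    for name, v in (("norm_acc", norm_acc), ("neuro_acc", neuro_acc), ("clf_acc", clf_acc)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} = {v} outside [0, 1]")
    if neuro_acc < norm_acc - 1e-12:
        raise ParameterError(
            "neuroadaptive accuracy below normative accuracy violates gate dominance"
        )
    added = neuro_acc - norm_acc
    corrected = norm_acc + clf_acc * added
    return UncertaintyReport(
        model="neuroadaptive-corrected",
        accuracy=neuro_acc,
        mu_epistemic=1.0 - corrected,
        mu_aleatory=(1.0 - clf_acc) * added,
        corrected_accuracy=corrected,
        classifier_accuracy=clf_acc,
    )


def paired_t(acc_a, acc_b) -> tuple[float, int, float]:
    """Paired-samples t-test on per-pilot accuracies; returns (t, df, p).

    Two-sided p. A zero-variance, zero-mean difference vector returns
    (0, df, 1) rather than NaN.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("need two equal-length vectors with n >= 2")
    d = b - a
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return float(np.inf) * np.sign(d.mean()), df, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


def cohens_d_av(acc_a, acc_b) -> float:
    """Cohen's d_av: mean difference over the average of the two sample SDs."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ParameterError("need two equal-length vectors with n >= 2")
    denom = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
    if denom == 0.0:
        raise DegenerateInputError("both vectors are constant; d_av undefined")
    return float((b - a).mean() / denom)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table; returns (chi2, df=1, p).

    Continuity (Yates) correction off by default; pass ``correction=True``
    for the corrected variant. A table with a zero margin returns (0, 1, 1):
    independence is untestable and trivially unrejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ParameterError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 0.0, 1, 1.0
    chi2, p, df, _ = sps.chi2_contingency(t, correction=correction)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# study aggregation
# ---------------------------------------------------------------------------

@dataclass
class PilotOutcome:
    """Everything one pilot contributes to the study report."""

    pilot_id: object
    normative: list[TraceOutcome]
    neuroadaptive: list[TraceOutcome] | None = None
    scores: dict[str, float] | None = None
    categories: dict[str, str] | None = None
    cv_accuracy: float | None = None


@dataclass
class StudyResult:
    """Aggregated study statistics with a statsmodels-style ``summary()``."""

    n_pilots: int
    n_events: int
    per_pilot: pd.DataFrame
    pooled_normative: float
    pooled_neuroadaptive: float | None
    uncertainty: list[UncertaintyReport]
    t_stat: float | None = None
    t_df: int | None = None
    t_p: float | None = None
    d_av: float | None = None
    chi2: float | None = None
    chi2_df: int | None = None
    chi2_p: float | None = None
    chi2_yates: float | None = None
    contingency: list[list[int]] | None = None
    n_unexplained: int | None = None
    degenerate_t: bool = False
    excluded_pilots: list = field(default_factory=list)
    classifier_accuracy: float | None = None

    def summary(self) -> str:
        lines = [
            "Neuroadaptive model-tracing study",
            "=================================",
            f"pilots analyzed        {self.n_pilots}"
            + (f"  (excluded: {self.excluded_pilots})" if self.excluded_pilots else ""),
            f"events analyzed        {self.n_events}",
            f"normative accuracy     {self.pooled_normative:.2f}"
            f"   (mu_epistemic = {1 - self.pooled_normative:.2f})",
        ]
        if self.pooled_neuroadaptive is not None:
            lines.append(
                f"neuroadaptive accuracy {self.pooled_neuroadaptive:.2f}"
                f"   (mu_epistemic = {1 - self.pooled_neuroadaptive:.2f})"
            )
            corr = next(
                (u for u in self.uncertainty if u.model == "neuroadaptive-corrected"), None
            )
            if corr is not None:
                lines.append(
                    f"corrected accuracy     {corr.corrected_accuracy:.2f}"
                    f"   (mu_epistemic = {corr.mu_epistemic:.2f},"
                    f" mu_aleatory = {corr.mu_aleatory:.2f},"
                    f" classifier = {corr.classifier_accuracy:.2f})"
                )
            if self.degenerate_t:
                lines.append("paired t               degenerate (no variance in differences)")
            elif self.t_stat is not None:
                lines.append(
                    f"paired t               t({self.t_df}) = {self.t_stat:.2f},"
                    f" p = {self.t_p:.3g}, d_av = "
                    + (f"{self.d_av:.2f}" if self.d_av is not None else "n/a")
                )
            if self.chi2 is not None:
                lines.append(
                    f"chi-square (response x score, N = {self.n_unexplained})"
                    f"   chi2(1) = {self.chi2:.2f}, p = {self.chi2_p:.3g}"
                    f"   [Yates: {self.chi2_yates:.2f}]"
                )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_pilots": self.n_pilots,
            "n_events": self.n_events,
            "pooled_normative": self.pooled_normative,
            "pooled_neuroadaptive": self.pooled_neuroadaptive,
            "uncertainty": [u.rounded(12) for u in self.uncertainty],
            "uncertainty_2dp": [u.rounded(2) for u in self.uncertainty],
            "t": None
            if self.t_stat is None
            else {"t": self.t_stat, "df": self.t_df, "p": self.t_p},
            "d_av": self.d_av,
            "chi2": None
            if self.chi2 is None
            else {
                "chi2": self.chi2,
                "df": self.chi2_df,
                "p": self.chi2_p,
                "yates": self.chi2_yates,
                "table": self.contingency,
                "n_unexplained": self.n_unexplained,
            },
            "degenerate_t": self.degenerate_t,
            "excluded_pilots": list(map(str, self.excluded_pilots)),
            "classifier_accuracy": self.classifier_accuracy,
            "per_pilot": self.per_pilot.to_dict(orient="list"),
        }


def build_study_report(
    pilots: list[PilotOutcome], classifier_accuracy: float | None = None
) -> StudyResult:
    """Aggregate per-pilot trace outcomes into the full study report.

    Pooled accuracies are fractions of correct classifications over *all*
    analyzable events; per-pilot accuracies feed the paired t-test and
    d_av. The contingency table crosses, over events the normative tracer
    left unexplained, the response type (omission / commission) with the
    classifier verdict (standard: score < 1.5 / target: score >= 1.5).
    Pilots with zero analyzable events are excluded with a warning.
    """
    kept, excluded = [], []
    for p in pilots:
        if len(p.normative) == 0:
            excluded.append(p.pilot_id)
        else:
            kept.append(p)
    if excluded:
        warnings.warn(f"excluded pilots with no analyzable events: {excluded}")
    if not kept:
        raise DegenerateInputError("no pilot contributed analyzable events")

    have_neuro = all(p.neuroadaptive is not None for p in kept)
    rows = []
    total_events = total_norm = total_neuro = 0
    for p in kept:
        n = len(p.normative)
        c_norm = sum(o.classification_correct for o in p.normative)
        row = {
            "pilot": p.pilot_id,
            "n_events": n,
            "normative_acc": c_norm / n,
            "cv_accuracy": p.cv_accuracy,
        }
        total_events += n
        total_norm += c_norm
        if have_neuro:
            c_neuro = sum(o.classification_correct for o in p.neuroadaptive)
            row["neuroadaptive_acc"] = c_neuro / n
            total_neuro += c_neuro
        rows.append(row)
    per_pilot = pd.DataFrame(rows)

    pooled_norm = total_norm / total_events
    uncertainty = [
        UncertaintyReport("normative", pooled_norm, mu_epistemic=1.0 - pooled_norm)
    ]
    result = StudyResult(
        n_pilots=len(kept),
        n_events=total_events,
        per_pilot=per_pilot,
        pooled_normative=pooled_norm,
        pooled_neuroadaptive=None,
        uncertainty=uncertainty,
        excluded_pilots=excluded,
        classifier_accuracy=classifier_accuracy,
    )
    if not have_neuro:
        return result

    pooled_neuro = total_neuro / total_events
    result.pooled_neuroadaptive = pooled_neuro
    uncertainty.append(
        UncertaintyReport("neuroadaptive", pooled_neuro, mu_epistemic=1.0 - pooled_neuro)
    )
    if classifier_accuracy is not None:
        uncertainty.append(
            decompose_uncertainty(pooled_norm, pooled_neuro, classifier_accuracy)
        )

    a = per_pilot["normative_acc"].to_numpy()
    b = per_pilot["neuroadaptive_acc"].to_numpy()
    if len(kept) >= 2:
        diffs = b - a
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            result.degenerate_t = True
            result.t_df = len(kept) - 1
        else:
            result.t_stat, result.t_df, result.t_p = paired_t(a, b)
            try:
                result.d_av = cohens_d_av(a, b)
            except DegenerateInputError:
                result.d_av = None

    # contingency over normatively unexplained events
    table = np.zeros((2, 2), dtype=int)  # rows: omission/commission; cols: standard/target
    for p in kept:
        if p.scores is None or p.categories is None:
            continue
        for o in p.normative:
            if o.classification_correct:
                continue
            cat = p.categories.get(o.event_id)
            score = p.scores.get(o.event_id)
            if cat not in ("omission", "commission") or score is None:
                continue
            i = 0 if cat == "omission" else 1
            j = 0 if score < RELEVANCE_GATE else 1
            table[i, j] += 1
    if table.sum() > 0:
        chi2, df, pval = chi_square_2x2(table, correction=False)
        chi2_y, _, _ = chi_square_2x2(table, correction=True)
        result.chi2, result.chi2_df, result.chi2_p = chi2, df, pval
        result.chi2_yates = chi2_y
        result.contingency = table.tolist()
        result.n_unexplained = int(table.sum())
    return result
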