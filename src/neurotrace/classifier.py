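"""Windowed-means features, shrinkage LDA and leakage-safe cross-validation.

The decoder is the classical single-trial ERP pipeline: per-channel mean
amplitudes over eight consecutive non-overlapping 50 ms windows starting at
150 ms post-marker form the feature vector (window-major order); a linear
discriminant with a shrinkage-regularized pooled covariance separates
task-irrelevant (standard) from task-relevant (target) responses. The
discriminant value is calibrated monotonically into [1, 2] with the decision
boundary at 1.5: below 1.5 an event counts as processed-as-irrelevant,
at or above 1.5 as task-relevant.

Because consecutive EEG trials are autocorrelated (overlapping filter edges,
slow drifts), accuracy is estimated with chronological contiguous folds and a
trial margin excluded from training on both sides of every test block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import binom
from sklearn.covariance import ledoit_wolf_shrinkage

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    ModelMismatchError,
    ParameterError,
)
from .prep import EpochSet

__all__ = [
    "FeatureConfig",
    "CVConfig",
    "RelevanceScore",
    "RelevanceModel",
    "RelevanceResults",
    "CVResult",
    "extract_windowed_means",
    "fit_shrinkage_lda",
    "cross_validate",
    "predict_relevance",
    "chance_threshold",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Windowed-means feature layout: ``n_windows`` consecutive non-overlapping
    windows of ``window_len_s`` starting ``start_s`` after the marker."""

    start_s: float = 0.150
    n_windows: int = 8
    window_len_s: float = 0.050

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.window_len_s <= 0 or self.n_windows < 1:
            raise ParameterError("feature windows must start at >= 0 with positive length")

    @property
    def end_s(self) -> float:
        return self.start_s + self.n_windows * self.window_len_s


@dataclass(frozen=True)
class CVConfig:
    """Chronological contiguous folds with a leakage margin: the
    ``margin_trials`` trials adjacent to each train/test boundary are removed
    from the training set (never from the test set)."""

    n_folds: int = 5
    margin_trials: int = 5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("need at least 2 folds")
        if self.margin_trials < 0:
            raise ParameterError("margin must be non-negative")


@dataclass(frozen=True)
class RelevanceScore:
    """Calibrated classifier output for one event: a value in [1, 2], where
    < 1.5 means the event was processed as task-irrelevant."""

    event_id: object
    value: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.value <= 2.0):
            raise ParameterError("relevance scores live in [1, 2]")

    @property
    def relevant(self) -> bool:
        # strict <1.5 irrelevance rule: exactly 1.5 counts as relevant
        return self.value >= 1.5


def extract_windowed_means(epochs: EpochSet, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Trial x feature matrix of windowed mean amplitudes.

    Feature order is window-major: feature ``w * n_channels + c`` is the mean
    of channel ``c`` over window ``w``. Sample windows are half-open.
    """
    t_min, _ = epochs.window
    fs = epochs.fs_hz
    onset = int(round(-t_min * fs))
    n_trials, n_ch, n_samp = epochs.epochs.shape
    feats = np.empty((n_trials, cfg.n_windows * n_ch))
    for w in range(cfg.n_windows):
        a = onset + int(round((cfg.start_s + w * cfg.window_len_s) * fs))
        b = onset + int(round((cfg.start_s + (w + 1) * cfg.window_len_s) * fs))
        if a < 0 or b > n_samp or b <= a:
            raise ConfigurationError(
                f"epoch window {epochs.window} too short for feature window {w} "
                f"([{cfg.start_s + w * cfg.window_len_s:.3f}, "
                f"{cfg.start_s + (w + 1) * cfg.window_len_s:.3f}) s)"
            )
        feats[:, w * n_ch : (w + 1) * n_ch] = epochs.epochs[:, :, a:b].mean(axis=2)
    return feats


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------

class RelevanceModel:
    """Binary shrinkage-LDA relevance decoder (model object).

    Parameters
    ----------
    X : (n_trials, n_features) feature matrix
    y : binary labels; the *larger* label is the task-relevant (target) class
    shrinkage : float in [0, 1] or "auto"
        Pooled covariance is shrunk toward a scaled identity,
        ``(1 - g) S + g (tr S / d) I``. "auto" picks g analytically with the
        Ledoit-Wolf estimator on class-centered data.
    """

    def __init__(self, X, y, shrinkage: float | str = "auto"):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ParameterError("X must be trials x features with one label per trial")
        classes = np.unique(y)
        if classes.size != 2:
            raise DegenerateInputError(f"need exactly 2 classes, got {classes.size}")
        if isinstance(shrinkage, str):
            if shrinkage != "auto":
                raise ParameterError("shrinkage must be a float in [0,1] or 'auto'")
        elif not (0.0 <= shrinkage <= 1.0):
            raise ParameterError("shrinkage must lie in [0, 1]")
        self.X, self.y, self.classes, self.shrinkage = X, y, classes, shrinkage

    @classmethod
    def from_epochs(
        cls, epochs: EpochSet, cfg: FeatureConfig = FeatureConfig(), shrinkage="auto"
    ) -> "RelevanceModel":
        model = cls(extract_windowed_means(epochs, cfg), epochs.labels, shrinkage)
        model._feature_config = cfg
        model._channel_labels = epochs.channel_labels
        return model

    def fit(self) -> "RelevanceResults":
        X, y = self.X, self.y
        c0, c1 = self.classes  # c1 = task-relevant class
        n0, n1 = int(np.sum(y == c0)), int(np.sum(y == c1))
        if min(n0, n1) < 2:
            raise DegenerateInputError("each class needs at least 2 trials")
        mu0 = X[y == c0].mean(axis=0)
        mu1 = X[y == c1].mean(axis=0)
        Xc = np.vstack([X[y == c0] - mu0, X[y == c1] - mu1])
        S = Xc.T @ Xc / (len(X) - 2)

        gamma = (
            float(ledoit_wolf_shrinkage(Xc, assume_centered=True))
            if self.shrinkage == "auto"
            else float(self.shrinkage)
        )
        d = X.shape[1]
        nu = np.trace(S) / d
        sigma = (1.0 - gamma) * S + gamma * nu * np.eye(d)
        try:
            w = np.linalg.solve(sigma, mu1 - mu0)
        except np.linalg.LinAlgError:
            w = np.linalg.pinv(sigma) @ (mu1 - mu0)
        # equal-prior boundary midway between the class discriminant means
        bias = -0.5 * float(w @ (mu0 + mu1))
        disc = X @ w + bias
        slope = _fit_calibration_slope(disc, (y == c1).astype(int))
        return RelevanceResults(
            weights=w,
            bias=bias,
            shrinkage=gamma,
            class_means=(mu0, mu1),
            pooled_cov=sigma,
            calibration_slope=slope,
            classes=(c0, c1),
            feature_config=getattr(self, "_feature_config", None),
            channel_labels=getattr(self, "_channel_labels", None),
        )


def _fit_calibration_slope(disc: np.ndarray, y01: np.ndarray) -> float:
    """Fit the logistic slope k of P(target | d) = sigmoid(k d) (intercept
    pinned at 0 so the decision boundary maps to exactly 1.5)."""
    scale = np.std(disc)
    if scale == 0:
        return 1.0
    kmax = 60.0 / scale  # saturate near-separable data instead of diverging

    def nll(logk: float) -> float:
        k = np.exp(logk)
        z = k * disc
        # stable log-likelihood of the logistic model
        return float(np.sum(np.logaddexp(0.0, -z) * y01 + np.logaddexp(0.0, z) * (1 - y01)))

    res = minimize_scalar(nll, bounds=(np.log(1e-6 / scale), np.log(kmax)), method="bounded")
    return float(np.exp(res.x))


@dataclass
class RelevanceResults:
    """Fitted relevance decoder: linear weights, shrunk pooled covariance and
    the monotone [1, 2] output calibration."""

    weights: np.ndarray
    bias: float
    shrinkage: float
    class_means: tuple[np.ndarray, np.ndarray]
    pooled_cov: np.ndarray
    calibration_slope: float
    classes: tuple
    feature_config: FeatureConfig | None = None
    channel_labels: list[str] | None = None

    @property
    def n_features(self) -> int:
        return self.weights.size

    def discriminant(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ModelMismatchError(
                f"model has {self.n_features} features, data has {X.shape[1]}"
            )
        return X @ self.weights + self.bias

    def relevance(self, X: np.ndarray) -> np.ndarray:
        """Calibrated scores in [1, 2]; 1.5 corresponds to the boundary."""
        return 1.0 + expit(self.calibration_slope * self.discriminant(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class decisions (irrelevant iff score < 1.5)."""
        return np.where(self.discriminant(X) >= 0.0, self.classes[1], self.classes[0])

    def summary(self) -> str:
        c0, c1 = self.classes
        lines = [
            "Shrinkage-LDA relevance decoder",
            "===============================",
            f"features            {self.n_features}",
            f"classes             irrelevant={c0}  relevant={c1}",
            f"shrinkage gamma     {self.shrinkage:.4f}",
            f"calibration slope   {self.calibration_slope:.4g}",
            f"|w|                 {np.linalg.norm(self.weights):.4g}",
            "decision            score >= 1.5 -> task-relevant",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "shrinkage": self.shrinkage,
            "calibration_slope": self.calibration_slope,
            "classes": [c.item() if hasattr(c, "item") else c for c in self.classes],
            "class_means": [m.tolist() for m in self.class_means],
            "feature_config": None
            if self.feature_config is None
            else {
                "start_s": self.feature_config.start_s,
                "n_windows": self.feature_config.n_windows,
                "window_len_s": self.feature_config.window_len_s,
            },
            "channel_labels": self.channel_labels,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RelevanceResults":
        d = json.loads(Path(path).read_text())
        w = np.asarray(d["weights"], dtype=float)
        fc = d["feature_config"]
        return cls(
            weights=w,
            bias=float(d["bias"]),
            shrinkage=float(d["shrinkage"]),
            class_means=tuple(np.asarray(m) for m in d["class_means"]),
            pooled_cov=np.eye(w.size),  # not serialized; inspection-only
            calibration_slope=float(d["calibration_slope"]),
            classes=tuple(d["classes"]),
            feature_config=None if fc is None else FeatureConfig(**fc),
            channel_labels=d["channel_labels"],
        )


def fit_shrinkage_lda(X, y, shrinkage: float | str = "auto") -> RelevanceResults:
    """Functional wrapper around ``RelevanceModel(X, y, shrinkage).fit()``."""
    return RelevanceModel(X, y, shrinkage).fit()


def predict_relevance(
    model: RelevanceResults, epochs: EpochSet | np.ndarray, event_ids=None
) -> list[RelevanceScore]:
    """Score epochs (or a ready feature matrix) with a fitted decoder."""
    if isinstance(epochs, EpochSet):
        cfg = model.feature_config or FeatureConfig()
        X = extract_windowed_means(epochs, cfg)
        if event_ids is None:
            event_ids = list(epochs.labels)
    else:
        X = np.atleast_2d(np.asarray(epochs, dtype=float))
        if event_ids is None:
            event_ids = list(range(X.shape[0]))
    values = np.clip(model.relevance(X), 1.0, 2.0)
    return [RelevanceScore(e, float(v)) for e, v in zip(event_ids, values)]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    mean_accuracy: float
    fold_accuracies: tuple[float, ...]
    n_test_trials: int


def cross_validate(
    X, y, cv: CVConfig = CVConfig(), shrinkage: float | str = "auto"
) -> CVResult:
    """Chronological k-fold CV with leakage margins.

    Trials are split into contiguous chronological blocks; for each test
    block, the ``margin_trials`` trials on either side of it are excluded
    from training. Accuracy is the fraction of correct hard decisions on the
    test trials, averaged over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < cv.n_folds:
        raise ParameterError(f"{n} trials cannot fill {cv.n_folds} folds")
    bounds = np.linspace(0, n, cv.n_folds + 1).astype(int)
    accs = []
    n_test = 0
    for i in range(cv.n_folds):
        a, b = bounds[i], bounds[i + 1]
        train_idx = np.r_[0 : max(a - cv.margin_trials, 0), min(b + cv.margin_trials, n) : n]
        test_idx = np.arange(a, b)
        if np.unique(y[train_idx]).size < 2:
            raise DegenerateInputError("a training split contains a single class")
        res = RelevanceModel(X[train_idx], y[train_idx], shrinkage).fit()
        pred = res.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        n_test += test_idx.size
    return CVResult(float(np.mean(accs)), tuple(accs), n_test)


# ---------------------------------------------------------------------------
# imbalance-aware chance level
# ---------------------------------------------------------------------------

def chance_threshold(n_trials: int, class_proportion: float, alpha: float = 0.05) -> float:
    """Smallest accuracy significantly above a majority-guessing null.

    The null guesser is correct with probability ``class_proportion`` (pass
    the majority-class proportion) on each of ``n_trials`` independent
    trials; the threshold is the smallest a = k/n with
    P(Binomial(n, p) >= k) <= alpha, by exact binomial tail. With imbalanced
    classes the chance level sits well above 50%.
    """
    if not (0.0 < alpha <= 1.0):
        raise ParameterError("alpha must lie in (0, 1]")
    if not (0.0 <= class_proportion <= 1.0):
        raise ParameterError("class proportion must lie in [0, 1]")
    if n_trials < 1:
        raise ParameterError("need at least one trial")
    if alpha == 1.0:
        return 0.0
    # smallest k with sf(k-1) = P(X >= k) <= alpha; may exceed n (threshold
    # > 1) when no attainable accuracy is significant at this n and p
    k = max(int(binom.isf(alpha, n_trials, class_proportion)), 0)
    while k <= n_trials and binom.sf(k - 1, n_trials, class_proportion) > alpha:
        k += 1
    while k > 0 and binom.sf(k - 2, n_trials, class_proportion) <= alpha:
        k -= 1
    return k / n_trials
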