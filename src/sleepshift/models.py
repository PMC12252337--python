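"""Population and personalized classifiers plus random-guess baselines.

Two classifier families satisfy the batch-fit + per-example-update contract:

* ``passive-aggressive`` — an online max-margin linear classifier
  (hinge-type updates, aggressiveness C = 1.0 by default);
* ``mlp`` — a feed-forward network with one hidden layer of 100 units.

A *population model* is trained once on the cohort and deployed frozen. A
*personalized model* starts from the same pretraining and is then updated
incrementally, one labelled example at a time, from the target user's
stream; it is scored prequentially (predict first, then learn). Feature
standardization statistics are frozen at pretraining and reused during
personalization.

Baselines: RG draws labels uniformly; BRG draws from the training-set label
distribution; PBRG additionally folds each observed stream label into that
distribution before the next draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .types import HIGH, LOW

__all__ = [
    "ClassifierSpec",
    "FittedModel",
    "PrequentialResult",
    "LabelDistribution",
    "SingleClassError",
    "train_population",
    "prequential_personalized",
    "rg_predict",
    "brg_predict",
    "pbrg_run",
    "pbrg_step",
]

CLASSES = np.array([HIGH, LOW])


class SingleClassError(ValueError):
    """The training set contains a single class."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to use, with hyperparameters and a seed."""

    family: str = "passive-aggressive"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def make(self, seed: int | None = None):
        rs = self.seed if seed is None else seed
        fam = self.family.lower()
        if fam in ("passive-aggressive", "pac", "online-max-margin-linear"):
            # PA-I: hinge loss, no regularization, passive-aggressive rate
            # with aggressiveness C = eta0.
            params = {
                "loss": "hinge",
                "penalty": None,
                "learning_rate": "pa1",
                "eta0": 1.0,
                "max_iter": 1000,
                "random_state": rs,
            }
            params.update(self.hyperparameters)
            return SGDClassifier(**params)
        if fam in ("mlp", "feedforward-network"):
            params = {
                "hidden_layer_sizes": (100,),
                "max_iter": 500,
                "early_stopping": False,
                "random_state": rs,
            }
            params.update(self.hyperparameters)
            return MLPClassifier(**params)
        raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class FittedModel:
    """A frozen scaler + classifier pair. Never mutated at prediction time."""

    scaler: StandardScaler
    clf: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self.scaler.transform(np.asarray(X, dtype=float)))


def train_population(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, seed: int | None = None
) -> FittedModel:
    """Fit a population model once on the available training data.

    Deterministic given the seed; raises :class:`SingleClassError` if only
    one class is present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training set contains a single class")
    scaler = StandardScaler().fit(X)
    clf = spec.make(seed)
    clf.fit(scaler.transform(X), y)
    return FittedModel(scaler=scaler, clf=clf)


@dataclass
class PrequentialResult:
    """Per-step prequential predictions and the resulting accuracy."""

    predictions: np.ndarray
    truths: np.ndarray
    accuracy: float | None  # None for an empty stream

    @property
    def correct(self) -> np.ndarray:
        return self.predictions == self.truths


def prequential_personalized(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_stream: np.ndarray,
    y_stream: np.ndarray,
    spec: ClassifierSpec,
    seed: int | None = None,
    stream_order: np.ndarray | None = None,
) -> PrequentialResult:
    """Pretrain on the cohort, then personalize prequentially on one user.

    For each stream element the model predicts first, the prediction is
    recorded, and only then is the model updated with the true label
    (interleaved test-then-train). ``stream_order`` — the chronological
    session indices — is checked to be strictly increasing to guard against
    temporal leakage.
    """
    if stream_order is not None:
        order = np.asarray(stream_order)
        if len(order) > 1 and np.any(np.diff(order) <= 0):
            raise ValueError(
                "stream is not in chronological order (temporal-leakage guard)"
            )
    model = train_population(X_train, y_train, spec, seed)
    X_stream = np.asarray(X_stream, dtype=float)
    y_stream = np.asarray(y_stream)
    preds = []
    for i in range(len(X_stream)):
        xi = model.scaler.transform(X_stream[i : i + 1])
        preds.append(model.clf.predict(xi)[0])
        model.clf.partial_fit(xi, y_stream[i : i + 1], classes=CLASSES)
    preds = np.array(preds)
    accuracy = float(np.mean(preds == y_stream)) if len(preds) else None
    return PrequentialResult(predictions=preds, truths=y_stream, accuracy=accuracy)


@dataclass
class LabelDistribution:
    """Counts of high/low labels and the implied probability of 'high'."""

    n_high: int = 0
    n_low: int = 0

    @classmethod
    def from_labels(cls, y) -> "LabelDistribution":
        y = np.asarray(y)
        return cls(n_high=int(np.sum(y == HIGH)), n_low=int(np.sum(y == LOW)))

    @property
    def p_high(self) -> float:
        total = self.n_high + self.n_low
        return self.n_high / total if total else 0.5

    def observe(self, label: str) -> "LabelDistribution":
        if label == HIGH:
            return LabelDistribution(self.n_high + 1, self.n_low)
        if label == LOW:
            return LabelDistribution(self.n_high, self.n_low + 1)
        raise ValueError(f"unknown label {label!r}")


def _draw(p_high: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.where(rng.random(n) < p_high, HIGH, LOW)


def rg_predict(n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Random guess: labels drawn uniformly."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return _draw(0.5, n, rng)


def brg_predict(
    dist: LabelDistribution, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Biased random guess: labels drawn from the frozen training distribution."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return _draw(dist.p_high, n, rng)


def pbrg_step(
    dist: LabelDistribution, observed_label: str
) -> LabelDistribution:
    """Update the label distribution with one observed stream label."""
    return dist.observe(observed_label)


def pbrg_run(
    dist: LabelDistribution, y_stream, rng: np.random.Generator | int
) -> np.ndarray:
    """Personalized biased random guess over a stream.

    Each prediction is drawn from the current distribution; the observed true
    label is folded in before the next draw.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    preds = []
    for label in np.asarray(y_stream):
        preds.append(_draw(dist.p_high, 1, rng)[0])
        dist = pbrg_step(dist, str(label))
    return np.array(preds, dtype=object) if preds else np.array([], dtype=object)
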