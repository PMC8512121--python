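"""Mixed-integer CNN hyperparameter search space for optimizer-driven design.

A candidate CNN is an 11-gene vector, ordered

    (CL, PL, FL, DL, FS, FN, UN, DR, AF, OF, LR)

= (conv layers, max-pool layers, dense layers, dropout layers, filter size,
filter count, hidden units, dropout rate, activation, optimizer, learning
rate).  Optimizers search a continuous box over these genes; a decode step
repairs out-of-box values by clamping and rounds each gene to its admissible
value (nearest integer for integer ranges, nearest member for the enumerated
filter-count and hidden-unit sets, ties to the smaller member, continuous
genes untouched).  Decoding is idempotent, so an optimizer sees plateaus
exactly where the discrete design space has them.

The default gene ranges: CL, PL in {2..6}; FL, DL in {1..3}; FS in {2..7};
FN in {16, 24, 32, 48, 64, 96, 128}; UN in {128, 192, 256, 384, 512};
DR in [0.1, 0.5]; AF in {1: ReLU, 2: ELU, 3: SELU, 4: LReLU}; OF in
{1: Adam, 2: Adamax, 3: Nadam, 4: Adagrad, 5: Adadelta, 6: SGD};
LR in [1e-4, 1e-2] (linear scale by default; a log-scale option exists).

Fitness is the classification error of the decoded architecture under a
pluggable backend.  The bundled deterministic surrogate stands in for GPU
training so the design loop is testable at desk scale; a Keras backend with
the real training protocol (80/20 split, 100 epochs, early stop after 3
stale epochs) is provided as a documented adapter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .problems import BoxProblem

__all__ = [
    "GENE_ORDER",
    "GeneSpec",
    "SearchSpace",
    "default_search_space",
    "HyperparamVector",
    "decode",
    "FitnessProtocol",
    "surrogate_fitness",
    "make_design_problem",
    "keras_fitness",
    "validate_architecture",
]

log = logging.getLogger(__name__)

GENE_ORDER = ("CL", "PL", "FL", "DL", "FS", "FN", "UN", "DR", "AF", "OF", "LR")

ACTIVATIONS = {1: "ReLU", 2: "ELU", 3: "SELU", 4: "LReLU"}
OPTIMIZERS = {1: "Adam", 2: "Adamax", 3: "Nadam", 4: "Adagrad", 5: "Adadelta", 6: "SGD"}


@dataclass(frozen=True)
class GeneSpec:
    """One gene: an integer range, an enumerated set, or a continuous range."""

    name: str
    kind: str  # "int" | "set" | "float"
    low: float
    high: float
    members: tuple[float, ...] | None = None

    def clamp(self, v: float) -> float:
        return min(max(float(v), self.low), self.high)

    def snap(self, v: float):
        """Clamp then round ``v`` to the nearest admissible value."""
        v = self.clamp(v)
        if self.kind == "float":
            return v
        if self.kind == "int":
            return _round_half_away(v)
        # enumerated set: nearest member, ties to the smaller member
        best = None
        best_d = math.inf
        for m in self.members:
            d = abs(v - m)
            if d < best_d - 1e-15:
                best, best_d = m, d
        return int(best)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of the 11 gene specifications."""

    genes: tuple[GeneSpec, ...]

    def __post_init__(self) -> None:
        if tuple(g.name for g in self.genes) != GENE_ORDER:
            raise ValueError(f"genes must be exactly {GENE_ORDER}, in order")

    @property
    def lower(self) -> np.ndarray:
        return np.array([g.low for g in self.genes])

    @property
    def upper(self) -> np.ndarray:
        return np.array([g.high for g in self.genes])

    def __getitem__(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


def default_search_space(log_lr: bool = False) -> SearchSpace:
    """The default design space (see module docstring for the ranges).

    ``log_lr=True`` searches the learning rate on a log10 scale (the gene
    then holds log10(LR)); off by default.
    """
    lr = (
        GeneSpec("LR", "float", math.log10(1e-4), math.log10(1e-2))
        if log_lr
        else GeneSpec("LR", "float", 1e-4, 1e-2)
    )
    return SearchSpace(
        genes=(
            GeneSpec("CL", "int", 2, 6),
            GeneSpec("PL", "int", 2, 6),
            GeneSpec("FL", "int", 1, 3),
            GeneSpec("DL", "int", 1, 3),
            GeneSpec("FS", "int", 2, 7),
            GeneSpec("FN", "set", 16, 128, (16, 24, 32, 48, 64, 96, 128)),
            GeneSpec("UN", "set", 128, 512, (128, 192, 256, 384, 512)),
            GeneSpec("DR", "float", 0.1, 0.5),
            GeneSpec("AF", "int", 1, 4),
            GeneSpec("OF", "int", 1, 6),
            lr,
        )
    )


@dataclass(frozen=True)
class HyperparamVector:
    """A decoded CNN design (typed genes plus named activation/optimizer)."""

    cl: int
    pl: int
    fl: int
    dl: int
    fs: int
    fn: int
    un: int
    dr: float
    af: int
    of: int
    lr: float

    @property
    def activation(self) -> str:
        return ACTIVATIONS[self.af]

    @property
    def optimizer(self) -> str:
        return OPTIMIZERS[self.of]

    def as_continuous(self) -> np.ndarray:
        """Re-embed into the continuous search box (decode is idempotent on it)."""
        return np.array(
            [self.cl, self.pl, self.fl, self.dl, self.fs, self.fn, self.un,
             self.dr, self.af, self.of, self.lr],
            dtype=float,
        )

    def to_dict(self) -> dict:
        return {
            "CL": self.cl, "PL": self.pl, "FL": self.fl, "DL": self.dl,
            "FS": self.fs, "FN": self.fn, "UN": self.un, "DR": self.dr,
            "AF": self.activation, "OF": self.optimizer, "LR": self.lr,
        }


def decode(v: np.ndarray, space: Optional[SearchSpace] = None) -> HyperparamVector:
    """Clamp and round a continuous 11-vector into a valid design."""
    space = space or default_search_space()
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != len(space.genes):
        raise ValueError(f"expected {len(space.genes)} genes, got {v.shape[0]}")
    vals = [g.snap(x) for g, x in zip(space.genes, v)]
    return HyperparamVector(*vals)


@dataclass(frozen=True)
class FitnessProtocol:
    """Training/evaluation protocol for a real fitness backend."""

    split: float = 0.8
    max_epochs: int = 100
    patience: int = 3


# -- surrogate backend --------------------------------------------------------

#: Relative weight of each gene's mismatch in the surrogate error surface.
#: Convolution depth and hidden-unit width dominate, mirroring which choices
#: move real validation accuracy the most.
_SURROGATE_WEIGHTS = {
    "CL": 0.22, "PL": 0.06, "FL": 0.08, "DL": 0.04, "FS": 0.08,
    "FN": 0.12, "UN": 0.18, "DR": 0.06, "AF": 0.05, "OF": 0.05, "LR": 0.06,
}


def surrogate_fitness(
    seed: int, base_error: float = 0.03, space: Optional[SearchSpace] = None
) -> Callable[[HyperparamVector], float]:
    """Deterministic stand-in for GPU training of a candidate CNN.

    A hidden "ideal" design is drawn once from ``seed``; a candidate's error
    is the base error plus a weighted normalized distance of its decoded
    genes from the ideal, plus a smooth multimodal ripple.  The surface is a
    function of the *decoded* design only, so continuous vectors that decode
    identically score identically (the plateaus of the true problem), and
    values stay within [0, 1].
    """
    space = space or default_search_space()
    rng = np.random.default_rng(seed)
    ideal = decode(space.lower + rng.random(11) * (space.upper - space.lower), space)
    ideal_v = ideal.as_continuous()
    lo, hi = space.lower, space.upper
    weights = np.array([_SURROGATE_WEIGHTS[g.name] for g in space.genes])
    freqs = 2.0 + rng.random(11) * 3.0  # per-gene ripple frequencies

    def error(hp: HyperparamVector) -> float:
        v = hp.as_continuous()
        z = (v - ideal_v) / (hi - lo)
        dist = float(np.sum(weights * np.abs(z)))
        # smooth multimodal ripple, exactly zero at the hidden ideal
        ripple = 0.02 * float(np.mean(np.sin(np.pi * freqs * z) ** 2))
        return float(np.clip(base_error + 0.9 * dist + ripple, 0.0, 1.0))

    error.ideal = ideal  # exposed for tests and demos
    return error


def make_design_problem(
    backend: Callable[[HyperparamVector], float],
    space: Optional[SearchSpace] = None,
    name: str = "cnn-design",
) -> BoxProblem:
    """Wrap a fitness backend as an 11-D box problem over the gene space.

    The objective decodes the continuous genes and returns the backend's
    classification error; a backend failure scores the worst possible error
    (1.0) with a logged warning, keeping the FFE accounting exact.
    """
    space = space or default_search_space()

    def objective(v: np.ndarray) -> float:
        hp = decode(v, space)
        try:
            return float(backend(hp))
        except Exception as exc:  # noqa: BLE001 - candidate failure is a score
            log.warning("fitness backend failed on %s: %r", hp.to_dict(), exc)
            return 1.0

    return BoxProblem(
        name=name,
        dimension=len(space.genes),
        lower=space.lower,
        upper=space.upper,
        objective=objective,
    )


# -- real (Keras) backend -----------------------------------------------------

def validate_architecture(hp: HyperparamVector, input_size: int = 128) -> bool:
    """Check that the decoded design yields a constructible network.

    2x2 max-pooling is attached after the first ``min(PL, CL)`` conv blocks;
    the feature map must stay at least 1x1 after all poolings.  At 128x128
    input with at most six poolings the map bottoms out at 2x2, so every
    in-space design is valid there; smaller inputs can collapse.
    """
    poolings = min(hp.pl, hp.cl)
    return input_size // (2 ** poolings) >= 1


def keras_fitness(
    dataset,
    protocol: FitnessProtocol = FitnessProtocol(),
    input_size: int = 128,
    num_classes: int = 4,
):
    """Fitness backend that builds and trains the decoded CNN with Keras.

    ``dataset`` is ``(x_train, y_train)`` as arrays; the train/validation
    split, epoch cap and early-stopping patience come from ``protocol``, and
    the returned error is the final validation classification error.  The
    architecture: ``CL`` conv blocks of ``FN`` filters of size ``FS x FS``
    (2x2 max-pooling after the first ``min(PL, CL)`` blocks), then ``FL``
    dense layers of ``UN`` units with dropout (rate ``DR``) after the first
    ``DL`` of them, softmax head, optimizer ``OF`` at learning rate ``LR``.

    Requires the optional tensorflow dependency; designs whose feature map
    collapses below 1x1 score the worst error without training.
    """
    import tensorflow as tf  # optional heavyweight dependency

    x, y = dataset

    def error(hp: HyperparamVector) -> float:
        if not validate_architecture(hp, input_size):
            return 1.0
        act = {"ReLU": "relu", "ELU": "elu", "SELU": "selu"}.get(hp.activation)
        layers = [tf.keras.layers.Input(shape=(input_size, input_size, 1))]
        poolings = min(hp.pl, hp.cl)
        for block in range(hp.cl):
            layers.append(
                tf.keras.layers.Conv2D(hp.fn, hp.fs, padding="same", activation=act)
                if act
                else tf.keras.layers.Conv2D(hp.fn, hp.fs, padding="same")
            )
            if act is None:  # LReLU has no string alias
                layers.append(tf.keras.layers.LeakyReLU())
            if block < poolings:
                layers.append(tf.keras.layers.MaxPooling2D(2))
        layers.append(tf.keras.layers.Flatten())
        for dense_idx in range(hp.fl):
            layers.append(tf.keras.layers.Dense(hp.un, activation=act or None))
            if act is None:
                layers.append(tf.keras.layers.LeakyReLU())
            if dense_idx < hp.dl:
                layers.append(tf.keras.layers.Dropout(hp.dr))
        layers.append(tf.keras.layers.Dense(num_classes, activation="softmax"))
        model = tf.keras.Sequential(layers)
        opt = getattr(tf.keras.optimizers, hp.optimizer)(learning_rate=hp.lr)
        model.compile(opt, "sparse_categorical_crossentropy", metrics=["accuracy"])
        stop = tf.keras.callbacks.EarlyStopping(
            monitor="val_accuracy", patience=protocol.patience
        )
        hist = model.fit(
            x, y,
            validation_split=1.0 - protocol.split,
            epochs=protocol.max_epochs,
            callbacks=[stop],
            verbose=0,
        )
        return 1.0 - float(hist.history["val_accuracy"][-1])

    return error
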