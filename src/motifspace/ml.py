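"""Fitness models on one-hot sequences and model-guided beam search.

Two data-split workflows are supported: a random disjoint train/test split
(fitness-landscape modelling) and a fitness split in which the sequences
with the highest CPM values are held out as testing and validation sets
(simulating a selection that missed the best variants). A fully connected
feed-forward network (scikit-learn MLPRegressor) maps one-hot encoded
sequences to CPM; a level-synchronous beam search then explores single-
mutation neighbourhoods under the model's guidance, and the search is
scored by precision - the fraction of the true top-k sequences recovered
among the search tree's top-k predictions (equal to recall since both sets
have size k).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor

from .iupac import BASES

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MLError(ValueError):
    pass


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def one_hot_encode(sequences: Sequence[str]) -> np.ndarray:
    """One-hot encode equal-length ACGT sequences, position-major, A<C<G<T.

    Each sequence maps to a binary row of length ``4 * L`` with exactly
    ``L`` ones. The encoding is invertible (:func:`one_hot_decode`).
    """
    seqs = list(sequences)
    if not seqs:
        raise MLError("no sequences to encode")
    L = len(seqs[0])
    out = np.zeros((len(seqs), 4 * L), dtype=np.float64)
    for r, s in enumerate(seqs):
        if len(s) != L:
            raise MLError("sequences must have equal length")
        for p, b in enumerate(s):
            try:
                out[r, 4 * p + _BASE_INDEX[b]] = 1.0
            except KeyError:
                raise MLError(f"ambiguous or invalid character {b!r} in {s!r}") from None
    return out


def one_hot_decode(matrix: np.ndarray) -> list[str]:
    """Invert :func:`one_hot_encode`."""
    mat = np.asarray(matrix)
    L = mat.shape[1] // 4
    out = []
    for row in mat.reshape(len(mat), L, 4):
        out.append("".join(BASES[int(k)] for k in row.argmax(axis=1)))
    return out


# ---------------------------------------------------------------------------
# data splits
# ---------------------------------------------------------------------------


def random_split(
    dataset: Mapping[str, float],
    train_frac: float = 0.1,
    test_frac: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Disjoint random train/test subsets of the requested fractions.

    Sizes are floors of ``frac * n``; sampling is uniform without
    replacement and reproducible by seed.
    """
    if not (0 < train_frac and 0 < test_frac and train_frac + test_frac <= 1):
        raise MLError("fractions must be positive and sum to at most 1")
    seqs = sorted(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    n_train = int(train_frac * len(seqs))
    n_test = int(test_frac * len(seqs))
    train_ids = [seqs[k] for k in perm[:n_train]]
    test_ids = [seqs[k] for k in perm[n_train : n_train + n_test]]
    return (
        {s: dataset[s] for s in train_ids},
        {s: dataset[s] for s in test_ids},
    )


def fitness_split(
    dataset: Mapping[str, float],
    n_test: int = 100,
    n_val: int = 100,
    train_sample_frac: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Hold out the top CPM sequences; sample the remainder for training.

    ``test`` is the ``n_test`` highest-CPM sequences, ``val`` the next
    ``n_val``; ``train`` is a random sample of ``train_sample_frac`` of the
    rest. CPM ties break by lexicographic sequence order. Returns
    ``(train, val, test)``.
    """
    if len(dataset) <= n_test + n_val:
        raise MLError(f"dataset of {len(dataset)} too small for {n_test}+{n_val} holdout")
    if not 0 < train_sample_frac <= 1:
        raise MLError("train_sample_frac must be in (0, 1]")
    ranked = sorted(dataset, key=lambda s: (-dataset[s], s))
    test_ids = ranked[:n_test]
    val_ids = ranked[n_test : n_test + n_val]
    rest = sorted(ranked[n_test + n_val :])
    rng = np.random.default_rng(seed)
    n_train = int(train_sample_frac * len(rest))
    train_ids = [rest[k] for k in rng.permutation(len(rest))[:n_train]]
    return (
        {s: dataset[s] for s in train_ids},
        {s: dataset[s] for s in val_ids},
        {s: dataset[s] for s in test_ids},
    )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperParams:
    """MLP hyperparameters explored by the grid search."""

    hidden_layer_sizes: tuple[int, ...] = (50, 50)
    learning_rate_init: float = 0.001
    batch_size: int = 100

    def __post_init__(self):
        if not self.hidden_layer_sizes or any(w <= 0 for w in self.hidden_layer_sizes):
            raise MLError("hidden layer widths must be positive")
        if self.learning_rate_init <= 0 or self.batch_size < 1:
            raise MLError("invalid learning rate or batch size")


#: default hyperparameter grid: 6 layer layouts x 3 learning rates x 2 batch
#: sizes = 36 combinations
DEFAULT_GRID: dict = {
    "hidden_layer_sizes": [
        (50, 50),
        (50, 50, 50),
        (100, 100),
        (100, 100, 100),
        (200, 200, 200),
        (100, 100, 100, 100),
    ],
    "learning_rate_init": [0.01, 0.001, 0.0001],
    "batch_size": [100, 200],
}


@dataclass
class FitnessModel:
    """A trained sequence-to-CPM regressor (fit/predict contract).

    Predictions are deterministic given the training data and seed. When
    trained with ``log_labels`` the regression target is log10 CPM and
    predictions are transformed back to the CPM scale.
    """

    regressor: MLPRegressor
    log_labels: bool
    metadata: dict = field(default_factory=dict)

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        pred = self.regressor.predict(one_hot_encode(sequences))
        if self.log_labels:
            pred = 10.0 ** pred
        return pred


def train_model(
    train_set: Mapping[str, float],
    hyperparams: HyperParams | None = None,
    seed: int = 0,
    log_labels: bool = False,
    max_iter: int = 300,
) -> FitnessModel:
    """Train an MLP regressor on one-hot sequences and CPM labels.

    Training is seeded; the returned model records hyperparameters, seed
    and a hash of the training set. ``log_labels`` regresses on log10 CPM
    (all labels must then be positive), which is numerically preferable
    when CPM spans several orders of magnitude.
    """
    if not train_set:
        raise MLError("empty training set")
    hp = hyperparams or HyperParams()
    seqs = sorted(train_set)
    y = np.array([train_set[s] for s in seqs], dtype=float)
    if np.isnan(y).any():
        raise MLError("NaN labels in training set")
    if log_labels:
        if (y <= 0).any():
            raise MLError("log-scale training requires positive labels")
        y = np.log10(y)
    X = one_hot_encode(seqs)
    reg = MLPRegressor(
        hidden_layer_sizes=hp.hidden_layer_sizes,
        learning_rate_init=hp.learning_rate_init,
        batch_size=min(hp.batch_size, len(seqs)),
        random_state=seed,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        reg.fit(X, y)
    digest = hashlib.sha256(
        json.dumps([[s, train_set[s]] for s in seqs]).encode()
    ).hexdigest()
    return FitnessModel(
        regressor=reg,
        log_labels=log_labels,
        metadata={
            "hyperparams": {
                "hidden_layer_sizes": list(hp.hidden_layer_sizes),
                "learning_rate_init": hp.learning_rate_init,
                "batch_size": hp.batch_size,
            },
            "seed": seed,
            "n_train": len(seqs),
            "train_hash": digest,
            "log_labels": log_labels,
        },
    )


def evaluate_regression(
    model: FitnessModel, test_set: Mapping[str, float]
) -> dict[str, float]:
    """Pearson and Spearman correlations of predicted vs observed CPM.

    Reported on the raw scale and (for positive pairs) on log10 CPM.
    """
    if len(test_set) < 3:
        raise MLError("need at least three test sequences")
    seqs = sorted(test_set)
    obs = np.array([test_set[s] for s in seqs], dtype=float)
    pred = model.predict(seqs)
    report = {
        "n": len(seqs),
        "pearson": float(stats.pearsonr(pred, obs).statistic),
        "spearman": float(stats.spearmanr(pred, obs).statistic),
    }
    pos = (obs > 0) & (pred > 0)
    if pos.sum() >= 3:
        report["pearson_log10"] = float(
            stats.pearsonr(np.log10(pred[pos]), np.log10(obs[pos])).statistic
        )
    return report


# ---------------------------------------------------------------------------
# beam search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamSearchParams:
    """The five beam-search parameters."""

    topN_start: int = 5
    beam_width: int = 5
    max_depth: int = 5
    top_explored: int = 100
    mode: str = "directed"

    def __post_init__(self):
        if min(self.topN_start, self.beam_width, self.top_explored) < 1 or self.max_depth < 0:
            raise MLError("beam parameters must be positive (max_depth >= 0)")
        if self.mode not in ("directed", "random"):
            raise MLError(f"mode must be 'directed' or 'random', got {self.mode!r}")

    def to_json(self) -> dict:
        return {
            "topN_start": self.topN_start,
            "beam_width": self.beam_width,
            "max_depth": self.max_depth,
            "top_explored": self.top_explored,
            "mode": self.mode,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "BeamSearchParams":
        return cls(**obj)


@dataclass(frozen=True)
class SearchNode:
    sequence: str
    predicted: float
    depth: int
    parent: str | None


@dataclass
class SearchTree:
    """All sequences scored during a beam search."""

    nodes: dict[str, SearchNode]

    def __len__(self) -> int:
        return len(self.nodes)

    def ranked(self, k: int | None = None) -> list[str]:
        order = sorted(
            self.nodes.values(), key=lambda n: (-n.predicted, n.sequence)
        )
        seqs = [n.sequence for n in order]
        return seqs if k is None else seqs[:k]


@dataclass
class BeamResult:
    tree: SearchTree
    top: list[str]
    params: BeamSearchParams


def _neighbors(seq: str, alphabet: Sequence[frozenset]) -> list[str]:
    out = []
    for p, allowed in enumerate(alphabet):
        for b in sorted(allowed):
            if b != seq[p]:
                out.append(seq[:p] + b + seq[p + 1 :])
    return out


def beam_search(
    model,
    seed_sequences: Sequence[str],
    params: BeamSearchParams,
    per_position_alphabet: Sequence[frozenset],
    exclude_set: frozenset = frozenset(),
    rng_seed: int = 0,
) -> BeamResult:
    """Level-synchronous model-guided search over single-mutation neighbours.

    The frontier starts as the seed sequences (the best training sequences).
    At each depth, every unvisited single-mutation neighbour of the frontier
    (within the per-position allowed alphabet, excluding ``exclude_set``) is
    scored by the model and added to the search tree; the ``beam_width``
    best-scoring mutants form the next frontier. In ``random`` mode the
    frontier is instead drawn uniformly from the scored candidates (the
    model still ranks the final output). The result lists the
    ``top_explored`` tree sequences ranked by predicted value, ties broken
    lexicographically.
    """
    seeds = sorted(set(seed_sequences))
    if not seeds:
        raise MLError("no seed sequences")
    L = len(seeds[0])
    if len(per_position_alphabet) != L:
        raise MLError("alphabet length must match sequence length")
    for s in seeds:
        if any(b not in a for b, a in zip(s, per_position_alphabet)):
            raise MLError(f"seed {s!r} not covered by the per-position alphabet")
    rng = np.random.default_rng(rng_seed)
    preds = model.predict(seeds)
    nodes = {
        s: SearchNode(s, float(v), 0, None) for s, v in zip(seeds, preds)
    }
    frontier = [
        n.sequence
        for n in sorted(nodes.values(), key=lambda n: (-n.predicted, n.sequence))
    ][: params.topN_start]
    visited = set(nodes)
    for depth in range(1, params.max_depth + 1):
        candidates: dict[str, str] = {}
        for f in frontier:
            for nb in _neighbors(f, per_position_alphabet):
                if nb not in visited and nb not in exclude_set and nb not in candidates:
                    candidates[nb] = f
        if not candidates:
            warnings.warn(f"frontier exhausted at depth {depth}; stopping early")
            break
        cand_seqs = sorted(candidates)
        scores = model.predict(cand_seqs)
        for s, v in zip(cand_seqs, scores):
            nodes[s] = SearchNode(s, float(v), depth, candidates[s])
        visited.update(cand_seqs)
        order = sorted(cand_seqs, key=lambda s: (-nodes[s].predicted, s))
        if params.mode == "directed":
            frontier = order[: params.beam_width]
        else:
            take = rng.choice(
                len(cand_seqs), size=min(params.beam_width, len(cand_seqs)), replace=False
            )
            frontier = [cand_seqs[int(k)] for k in sorted(take)]
    tree = SearchTree(nodes)
    return BeamResult(tree=tree, top=tree.ranked(params.top_explored), params=params)


def precision(found_top: Sequence[str], true_top: Sequence[str]) -> float:
    """|found ∩ true| / k for two size-k lists (equals recall by symmetry)."""
    if len(found_top) != len(true_top):
        raise MLError(
            f"lists must have equal nominal size, got {len(found_top)} and {len(true_top)}"
        )
    if not found_top:
        raise MLError("empty lists")
    return len(set(found_top) & set(true_top)) / len(found_top)


def fraction_explored(tree: SearchTree, n_encoded_absent: int) -> float:
    """Search-tree size over the number of encoded-but-absent sequences."""
    if n_encoded_absent <= 0:
        raise MLError("n_encoded_absent must be positive")
    return len(tree) / n_encoded_absent


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def grid_search(
    train_set: Mapping[str, float],
    val_set: Mapping[str, float],
    per_position_alphabet: Sequence[frozenset],
    grid: Mapping[str, Sequence] | None = None,
    beam_params: BeamSearchParams | None = None,
    seed: int = 0,
    log_labels: bool = True,
    max_iter: int = 300,
) -> tuple[HyperParams, pd.DataFrame]:
    """End-to-end hyperparameter grid search scored by beam-search precision.

    Trains one model per grid combination, runs the beam search with fixed
    beam parameters from the best training sequences, and evaluates
    precision against the validation set's top sequences. Returns the best
    combination (ties: first in grid order) and the full results table.
    """
    grid = dict(grid or DEFAULT_GRID)
    beam_params = beam_params or BeamSearchParams(
        top_explored=min(100, len(val_set))
    )
    val_top = sorted(val_set, key=lambda s: (-val_set[s], s))[: beam_params.top_explored]
    seeds_pool = sorted(train_set, key=lambda s: (-train_set[s], s))
    rows = []
    best: tuple[float, int] | None = None  # (-precision, order index)
    best_hp = None
    keys = list(grid)
    for order, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        kwargs = dict(zip(keys, combo))
        hp = HyperParams(
            hidden_layer_sizes=tuple(kwargs["hidden_layer_sizes"]),
            learning_rate_init=kwargs["learning_rate_init"],
            batch_size=kwargs["batch_size"],
        )
        model = train_model(
            train_set, hp, seed=seed, log_labels=log_labels, max_iter=max_iter
        )
        result = beam_search(
            model,
            seeds_pool[: beam_params.topN_start],
            beam_params,
            per_position_alphabet,
            rng_seed=seed,
        )
        prec = precision(result.top, val_top)
        rows.append(
            {
                "hidden_layer_sizes": str(hp.hidden_layer_sizes),
                "learning_rate_init": hp.learning_rate_init,
                "batch_size": hp.batch_size,
                "precision": prec,
            }
        )
        key = (-prec, order)
        if best is None or key < best:
            best, best_hp = key, hp
    return best_hp, pd.DataFrame(rows)
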