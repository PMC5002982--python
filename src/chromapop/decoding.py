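"""Cross-condition invariant decoding from population responses.

Two families of generalization problems probe whether hue and luminance
are represented in a separable, invariant way:

* hue generalization — for every pair of the 17 hue-matched hues, a
  maximum-margin linear classifier is trained to separate the two hues
  from their population responses at two luminance classes (4 training
  points) and tested on the held-out third class (2 test points);
* luminance generalization — for every held-out pair of hues, the
  classifier is trained to separate two luminance classes from the
  remaining 15 hues (30 points) and tested on the 4 held-out points.

Responses are z-scored per neuron within the 51-stimulus hue-matched
subset before decoding. Chance is 50% by construction; significance
comes from a training-label permutation null, and paired accuracy
comparisons between populations use McNemar's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .config import LUMINANCE_CLASSES
from .geometry import zscore_rates
from .synth import ResponseMatrix

CLASS_INDEX = {c: i for i, c in enumerate(LUMINANCE_CLASSES)}
SVM_C = 1.0  # fixed regularization; problems are (near-)separable by design


@dataclass
class DecodingResult:
    problem: str
    accuracy_mean: float
    accuracy_sd_over_subsamples: float | None = None
    p_perm: float | None = None
    n_subsample_runs: int | None = None


def hue_matched_tensor(pop: ResponseMatrix, table: pd.DataFrame):
    """Z-scored responses arranged as (n_triplets, 3 classes, n_neurons).

    Neurons are z-scored jointly across all 51 hue-matched stimuli (the
    default convention); stimulus order within the tensor follows
    ascending triplet id, classes in (low, equi, high) order.
    """
    trip = table.dropna(subset=["triplet_id"]).copy()
    if trip.empty:
        raise ValueError("stimulus table has no hue-matched triplets")
    trip["triplet_id"] = trip["triplet_id"].astype(int)
    id_to_col = {sid: j for j, sid in enumerate(pop.stimulus_ids)}
    missing = [s for s in trip["stimulus_id"] if s not in id_to_col]
    if missing:
        raise ValueError(f"responses missing for stimuli: {missing[:5]}")
    cols = [id_to_col[s] for s in trip["stimulus_id"]]
    z = zscore_rates(pop.rates[:, cols])  # neurons x 51
    trip_ids = sorted(trip["triplet_id"].unique())
    tensor = np.empty((len(trip_ids), 3, z.shape[0]))
    pos = {s: j for j, s in enumerate(trip["stimulus_id"])}
    for ti, tid in enumerate(trip_ids):
        g = trip[trip["triplet_id"] == tid]
        if set(g["luminance_class"]) != set(LUMINANCE_CLASSES):
            raise ValueError(f"triplet {tid} is missing a luminance class")
        for _, row in g.iterrows():
            tensor[ti, CLASS_INDEX[row["luminance_class"]]] = (
                z[:, pos[row["stimulus_id"]]]
            )
    return tensor, trip_ids


def _fit_predict(x_train, y_train, x_test):
    clf = LinearSVC(C=SVM_C, tol=1e-5, max_iter=20000)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def hue_generalization(tensor: np.ndarray, test_class: str,
                       rng: np.random.Generator | None = None):
    """Mean pairwise hue accuracy generalizing to ``test_class``.

    When ``rng`` is given, the 4 training labels of every pair are
    shuffled (the permutation-null variant). Returns (mean_accuracy,
    correctness) with one flag per test point.
    """
    t = CLASS_INDEX[test_class]
    train_classes = [c for c in range(3) if c != t]
    n_trip = tensor.shape[0]
    correct = []
    for h1, h2 in combinations(range(n_trip), 2):
        x_train = np.vstack([tensor[h, c] for h in (h1, h2)
                             for c in train_classes])
        y_train = np.array([0, 0, 1, 1])
        if rng is not None:
            y_train = rng.permutation(y_train)
        x_test = np.vstack([tensor[h1, t], tensor[h2, t]])
        pred = _fit_predict(x_train, y_train, x_test)
        correct.extend(pred == np.array([0, 1]))
    correct = np.asarray(correct, dtype=bool)
    return float(correct.mean()), correct


def luminance_generalization(tensor: np.ndarray, class_a: str, class_b: str,
                             rng: np.random.Generator | None = None):
    """Mean luminance-classification accuracy over held-out hue pairs.

    Trains on 15 of 17 hues (two luminance classes, 30 points), tests on
    the 4 points of the held-out hue pair. ``rng`` shuffles training
    labels for the permutation null. Returns (mean_accuracy, correctness).
    """
    a, b = CLASS_INDEX[class_a], CLASS_INDEX[class_b]
    n_trip = tensor.shape[0]
    correct = []
    for h1, h2 in combinations(range(n_trip), 2):
        train_h = [h for h in range(n_trip) if h not in (h1, h2)]
        x_train = np.vstack([tensor[h, c] for h in train_h for c in (a, b)])
        y_train = np.tile([0, 1], len(train_h))
        if rng is not None:
            y_train = rng.permutation(y_train)
        x_test = np.vstack([tensor[h, c] for h in (h1, h2) for c in (a, b)])
        pred = _fit_predict(x_train, y_train, x_test)
        correct.extend(pred == np.array([0, 1, 0, 1]))
    correct = np.asarray(correct, dtype=bool)
    return float(correct.mean()), correct


def permutation_null(decode_fn, observed: float, n_perm: int = 200,
                     seed: int = 0):
    """Training-label permutation test for a decoding accuracy.

    ``decode_fn(rng)`` must rerun the full decoding procedure with the
    given generator shuffling training labels. p is add-one:
    (1 + #{null >= observed}) / (1 + n_perm); with 200 permutations the
    smallest reportable value is bounded near 1/200.
    """
    rng = np.random.default_rng(seed)
    null = np.array([decode_fn(rng)[0] for _ in range(n_perm)])
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return float(p), null


def subsample_and_decode(pop_tensor: np.ndarray, n_sub: int, runs: int,
                         decode_fn, seed: int = 0) -> np.ndarray:
    """Accuracy distribution over random neuron subsamples.

    ``decode_fn(tensor)`` computes one accuracy; ``pop_tensor`` is the
    full (triplets, classes, neurons) array. Raises when the population
    is smaller than ``n_sub``.
    """
    n_neurons = pop_tensor.shape[2]
    if n_neurons < n_sub:
        raise ValueError("population smaller than requested subsample")
    rng = np.random.default_rng(seed)
    out = np.empty(runs)
    for i in range(runs):
        idx = rng.choice(n_neurons, size=n_sub, replace=False)
        out[i] = decode_fn(pop_tensor[:, :, idx])
    return out


def mcnemar_exact(outcomes_a, outcomes_b) -> float:
    """Exact two-tailed McNemar test on paired correctness flags.

    Uses only the discordant pairs: with b = #(a correct, b wrong) and
    c = #(a wrong, b correct), p = 2 * min tail of Binomial(b + c, 1/2),
    capped at 1. Returns 1.0 when there are no discordant pairs.
    """
    a = np.asarray(outcomes_a, dtype=bool)
    b = np.asarray(outcomes_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired outcome vectors must have equal length")
    n_b = int(np.sum(a & ~b))
    n_c = int(np.sum(~a & b))
    n = n_b + n_c
    if n == 0:
        return 1.0
    k = min(n_b, n_c)
    p = 2.0 * stats.binom.cdf(k, n, 0.5)
    return float(min(p, 1.0))
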