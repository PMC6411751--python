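"""Laplacian-corrected naive Bayesian classifier for sparse chemical features.

The classifier scores a molecule by summing per-feature log weights

    w_i = ln[ ((A_i + p K) / (T_i + K)) / p ],      K = 1 / p,

where ``A_i`` and ``T_i`` are the number of active and total training
molecules carrying feature ``i`` and ``p`` is the base active rate.  With
K = 1/p this simplifies to ``w_i = ln[(A_i + 1) / ((T_i + 1/p) p)]``: a
feature sampled at the base rate gets weight exactly zero, and a feature seen
only once moves the estimate minimally — the Laplacian correction assumes
most features carry no activity signal.

Raw scores are normalized by the molecule's feature count so that score
distributions are comparable across molecule sizes; the class probability
EstPGood is then a two-Gaussian posterior built from the training set's
leave-one-out score distributions.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .chem_io import ACTIVE, INACTIVE, Featurizer, MoleculeRecord, MoleculeSet

SIGMA_FLOOR = 1e-6


def feature_weight(a_i: int, t_i: int, p_good: float) -> float:
    """Laplacian-corrected log weight of one feature.

    Requires 0 <= a_i <= t_i, t_i >= 1 and p_good in (0, 1).  Features absent
    from training never enter this call; they contribute weight 0 upstream.
    """
    if t_i < 1:
        raise ValueError("t_i must be >= 1 (unseen features get weight 0 upstream)")
    if not 0 <= a_i <= t_i:
        raise ValueError(f"need 0 <= a_i <= t_i, got a_i={a_i}, t_i={t_i}")
    if not 0.0 < p_good < 1.0:
        raise ValueError(f"p_good must be in (0,1), got {p_good}")
    return math.log((a_i + 1.0) / ((t_i + 1.0 / p_good) * p_good))


def normalized_score(raw: float, n_features: int) -> float:
    """Raw weight sum divided by max(1, molecule feature count)."""
    return raw / max(1, n_features)


def _feature_counts(
    features: Sequence[frozenset[int]], y: Sequence[int]
) -> tuple[dict[int, int], dict[int, int]]:
    active_counts: dict[int, int] = {}
    total_counts: dict[int, int] = {}
    for feats, label in zip(features, y):
        for f in feats:
            total_counts[f] = total_counts.get(f, 0) + 1
            if label:
                active_counts[f] = active_counts.get(f, 0) + 1
    return active_counts, total_counts


def _clipped_p_good(n_active: int, n_total: int) -> float:
    # Degenerate single-class folds (possible inside LOO) are kept scoreable
    # by clipping the base rate away from {0, 1}.
    eps = 0.5 / max(1, n_total)
    return float(np.clip(n_active / max(1, n_total), eps, 1.0 - eps))


def train_from_features(
    features: Sequence[frozenset[int]], y: Sequence[int]
) -> tuple[dict[int, float], float]:
    """Weights and base rate from pre-computed feature sets and 0/1 labels."""
    n_total = len(y)
    p_good = _clipped_p_good(int(sum(y)), n_total)
    active_counts, total_counts = _feature_counts(features, y)
    weights = {
        f: feature_weight(active_counts.get(f, 0), t, p_good) for f, t in total_counts.items()
    }
    return weights, p_good


def score_features(weights: Mapping[int, float], feats: frozenset[int]) -> tuple[float, float]:
    """(raw, normalized) score; features unseen in training contribute 0."""
    raw = sum(weights[f] for f in feats if f in weights)
    return raw, normalized_score(raw, len(feats))


def loo_scores_from_features(
    features: Sequence[frozenset[int]], y: Sequence[int]
) -> list[float]:
    """Exact leave-one-out normalized scores by count decrement.

    For each record the model trained on the remaining n-1 records is
    recovered exactly by decrementing the held-out record's feature counts
    and class totals; a feature whose total count drops to zero is unseen by
    the reduced model and contributes nothing.  Equivalent to naive
    retrain-per-record to full precision.
    """
    n_total = len(y)
    n_active = int(sum(y))
    active_counts, total_counts = _feature_counts(features, y)
    out = []
    for feats, label in zip(features, y):
        p = _clipped_p_good(n_active - label, n_total - 1)
        raw = 0.0
        for f in feats:
            t = total_counts[f] - 1
            if t < 1:
                continue
            raw += feature_weight(active_counts.get(f, 0) - label, t, p)
        out.append(normalized_score(raw, len(feats)))
    return out


def _choose_threshold(scores: Sequence[float], y: Sequence[int]) -> float:
    """Normalized-score cut minimizing total LOO misclassifications.

    Candidate cuts are midpoints between adjacent distinct scores plus one
    cut below the minimum and one above the maximum; ties in error count go
    to the lowest cut.  A record is called active iff its score exceeds the
    cut.
    """
    distinct = sorted(set(scores))
    candidates = [distinct[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
    candidates += [distinct[-1] + 1.0]
    scores_arr = np.asarray(scores)
    y_arr = np.asarray(y)
    best_cut, best_err = candidates[0], None
    for cut in candidates:
        err = int(np.sum((scores_arr > cut) != y_arr))
        if best_err is None or err < best_err:
            best_cut, best_err = cut, err
    return float(best_cut)


@dataclass(frozen=True)
class Prediction:
    """Scores and class call for one molecule under one model."""

    raw_score: float
    normalized_score: float
    est_p_good: float
    binary_call: str


@dataclass
class BayesModel:
    """Trained Laplacian-corrected naive Bayes model.

    Carries per-feature weights, the base active rate, the Gaussian
    parameters of the two classes' leave-one-out score distributions (used by
    :meth:`est_p_good`), the decision threshold and the frozen featurization
    config.
    """

    p_good: float
    weights: dict[int, float]
    mu_active: float
    sigma_active: float
    mu_inactive: float
    sigma_inactive: float
    threshold: float
    featurizer: Featurizer
    training_ids: list[str] = field(default_factory=list)
    training_labels: list[str] = field(default_factory=list)

    # -- scoring ------------------------------------------------------------

    def score(self, feats: frozenset[int]) -> tuple[float, float]:
        return score_features(self.weights, feats)

    def est_p_good(self, s: float) -> float:
        """Two-Gaussian class probability of the active class at score ``s``.

        EstPGood = phi(s; mu_A, sigma_A) / (phi(s; mu_A, sigma_A) +
        phi(s; mu_I, sigma_I)), evaluated in log space so that far-tail
        scores never produce NaN.
        """
        log_a = norm.logpdf(s, self.mu_active, self.sigma_active)
        log_i = norm.logpdf(s, self.mu_inactive, self.sigma_inactive)
        return float(expit(log_a - log_i))

    def predict_features(self, feats: frozenset[int]) -> Prediction:
        raw, s = self.score(feats)
        return Prediction(
            raw_score=raw,
            normalized_score=s,
            est_p_good=self.est_p_good(s),
            binary_call=ACTIVE if s > self.threshold else INACTIVE,
        )

    def predict(self, record: MoleculeRecord) -> Prediction:
        return self.predict_features(self.featurizer.transform(record))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "p_good": self.p_good,
            "weights": {str(k): v for k, v in self.weights.items()},
            "mu_active": self.mu_active,
            "sigma_active": self.sigma_active,
            "mu_inactive": self.mu_inactive,
            "sigma_inactive": self.sigma_inactive,
            "threshold": self.threshold,
            "featurizer": self.featurizer.to_dict(),
            "training_ids": self.training_ids,
            "training_labels": self.training_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BayesModel":
        return cls(
            p_good=float(d["p_good"]),
            weights={int(k): float(v) for k, v in d["weights"].items()},
            mu_active=float(d["mu_active"]),
            sigma_active=float(d["sigma_active"]),
            mu_inactive=float(d["mu_inactive"]),
            sigma_inactive=float(d["sigma_inactive"]),
            threshold=float(d["threshold"]),
            featurizer=Featurizer.from_dict(d["featurizer"]),
            training_ids=list(d.get("training_ids", [])),
            training_labels=list(d.get("training_labels", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "BayesModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _labels_to_binary(dataset: MoleculeSet) -> list[int]:
    labels = dataset.labels
    if labels is None:
        raise ValueError("dataset must carry activity labels")
    y = [1 if l == ACTIVE else 0 for l in labels]
    if sum(y) < 2 or len(y) - sum(y) < 2:
        raise ValueError("training needs at least 2 actives and 2 inactives")
    return y


def train(dataset: MoleculeSet, featurizer: Featurizer | None = None) -> BayesModel:
    """Train a model on a labeled, standardized molecule set.

    Fits the descriptor binning scheme on the training molecules, computes
    Laplacian-corrected weights for every observed feature, evaluates exact
    leave-one-out normalized scores for each record, estimates the Gaussian
    parameters of the two classes' LOO score distributions (sd floored at
    1e-6), and picks the decision threshold minimizing LOO misclassification.
    """
    y = _labels_to_binary(dataset)
    if not all(r.standardized for r in dataset.records):
        raise ValueError("all training records must be standardized")
    featurizer = featurizer or Featurizer()
    features = featurizer.fit_transform(dataset.records)
    weights, p_good = train_from_features(features, y)
    loo = loo_scores_from_features(features, y)
    loo_arr = np.asarray(loo)
    y_arr = np.asarray(y, dtype=bool)
    mu_a = float(loo_arr[y_arr].mean())
    mu_i = float(loo_arr[~y_arr].mean())
    sd_a = max(float(loo_arr[y_arr].std(ddof=1)), SIGMA_FLOOR)
    sd_i = max(float(loo_arr[~y_arr].std(ddof=1)), SIGMA_FLOOR)
    return BayesModel(
        p_good=p_good,
        weights=weights,
        mu_active=mu_a,
        sigma_active=sd_a,
        mu_inactive=mu_i,
        sigma_inactive=sd_i,
        threshold=_choose_threshold(loo, y),
        featurizer=featurizer,
        training_ids=dataset.ids,
        training_labels=list(dataset.labels or []),
    )


def loo_scores(dataset: MoleculeSet, featurizer: Featurizer | None = None) -> list[float]:
    """Exact per-record leave-one-out normalized scores, in input order."""
    y = _labels_to_binary(dataset)
    featurizer = featurizer or Featurizer()
    features = featurizer.fit_transform(dataset.records)
    return loo_scores_from_features(features, y)
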