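"""Model validation: leave-one-out ROC, label-randomization null, k-fold CV.

All three procedures operate on the exact leave-one-out machinery of
:mod:`orco_vscreen.bayes` (count decrement, no approximation).  Featurization
is performed once per dataset — the descriptor binning scheme is a property
of the molecules, not of the labels — so label permutations and fold splits
reuse cached feature sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .bayes import (
    _labels_to_binary,
    loo_scores_from_features,
    score_features,
    train_from_features,
)
from .chem_io import Featurizer, MoleculeSet


@dataclass(frozen=True)
class RocResult:
    """AUC with class sizes and the number of tied active-inactive pairs."""

    auc: float
    n_active: int
    n_inactive: int
    tie_count: int


@dataclass(frozen=True)
class NullDistribution:
    """Mean/sd of LOO AUC over label permutations."""

    mean_auc: float
    sd_auc: float
    n_reps: int
    seed: int


@dataclass(frozen=True)
class KFoldResult:
    """Repeated stratified k-fold summary."""

    k: int
    n_reps: int
    mean_auc: float
    sd_auc: float
    dropped_per_rep: int
    seed: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Mann-Whitney AUC: (#concordant + 0.5 #tied) / (n_active n_inactive).

    ``labels`` are 0/1 (inactive/active).  Tied active-inactive score pairs
    receive half credit, the standard convention.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_act = int(y.sum())
    n_inact = int(len(y) - n_act)
    if n_act == 0 or n_inact == 0:
        raise ValueError("ROC needs at least one record of each class")
    auc = float(roc_auc_score(y, s))
    ties = 0
    vals, counts = np.unique(s, return_counts=True)
    for v, c in zip(vals, counts):
        if c > 1:
            a = int(y[s == v].sum())
            ties += a * (c - a)
    return RocResult(auc=auc, n_active=n_act, n_inactive=n_inact, tie_count=ties)


def _features_and_labels(
    dataset: MoleculeSet, featurizer: Featurizer | None
) -> tuple[list[frozenset[int]], list[int]]:
    y = _labels_to_binary(dataset)
    featurizer = featurizer or Featurizer()
    return featurizer.fit_transform(dataset.records), y


def loo_roc(dataset: MoleculeSet, featurizer: Featurizer | None = None) -> RocResult:
    """ROC over exact leave-one-out normalized scores."""
    features, y = _features_and_labels(dataset, featurizer)
    return roc_auc(loo_scores_from_features(features, y), y)


def randomization_null(
    dataset: MoleculeSet,
    n_reps: int = 100,
    seed: int = 0,
    featurizer: Featurizer | None = None,
) -> NullDistribution:
    """LOO AUC distribution after uniform label permutation (y-randomization).

    Class sizes are preserved; each repetition permutes the labels, retrains
    (via count decrement) and computes the LOO AUC.  Reproducible from seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    features, y = _features_and_labels(dataset, featurizer)
    rng = np.random.default_rng(seed)
    y_arr = np.asarray(y)
    aucs = []
    for _ in range(n_reps):
        perm = rng.permutation(y_arr)
        scores = loo_scores_from_features(features, perm.tolist())
        aucs.append(roc_auc(scores, perm.tolist()).auc)
    aucs_arr = np.asarray(aucs)
    sd = float(aucs_arr.std(ddof=1)) if n_reps > 1 else 0.0
    return NullDistribution(mean_auc=float(aucs_arr.mean()), sd_auc=sd, n_reps=n_reps, seed=seed)


def kfold_cv(
    dataset: MoleculeSet,
    k: int,
    n_reps: int = 1000,
    seed: int = 0,
    featurizer: Featurizer | None = None,
) -> KFoldResult:
    """Repeated stratified k-fold cross-validation.

    Per repetition each class is shuffled independently and split into k
    equal bins by floor division; leftover records (class size mod k) are
    dropped for that repetition — reshuffling across repetitions ensures no
    compound is left out altogether.  Each bin serves once as the test set,
    the fold AUCs are averaged, and the mean/sd across repetitions is
    returned.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    features, y = _features_and_labels(dataset, featurizer)
    y_arr = np.asarray(y)
    act_idx = np.flatnonzero(y_arr == 1)
    inact_idx = np.flatnonzero(y_arr == 0)
    if len(act_idx) < k or len(inact_idx) < k:
        raise ValueError(f"each class needs at least k={k} members")
    dropped = int(len(act_idx) % k + len(inact_idx) % k)
    rng = np.random.default_rng(seed)
    rep_aucs = []
    for _ in range(n_reps):
        act_perm = rng.permutation(act_idx)
        inact_perm = rng.permutation(inact_idx)
        a_bin, i_bin = len(act_idx) // k, len(inact_idx) // k
        fold_aucs = []
        for fold in range(k):
            test_idx = np.concatenate(
                [
                    act_perm[fold * a_bin : (fold + 1) * a_bin],
                    inact_perm[fold * i_bin : (fold + 1) * i_bin],
                ]
            )
            train_idx = np.concatenate(
                [
                    act_perm[: fold * a_bin],
                    act_perm[(fold + 1) * a_bin : k * a_bin],
                    inact_perm[: fold * i_bin],
                    inact_perm[(fold + 1) * i_bin : k * i_bin],
                ]
            )
            weights, _ = train_from_features(
                [features[i] for i in train_idx], y_arr[train_idx].tolist()
            )
            scores = [score_features(weights, features[i])[1] for i in test_idx]
            fold_aucs.append(roc_auc(scores, y_arr[test_idx].tolist()).auc)
        rep_aucs.append(float(np.mean(fold_aucs)))
    rep_arr = np.asarray(rep_aucs)
    sd = float(rep_arr.std(ddof=1)) if n_reps > 1 else 0.0
    return KFoldResult(
        k=k,
        n_reps=n_reps,
        mean_auc=float(rep_arr.mean()),
        sd_auc=sd,
        dropped_per_rep=dropped,
        seed=seed,
    )
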