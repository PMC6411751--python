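"""Dual-model virtual screening, gating, diversity clustering and novelty.

A library is scored under two classifiers (one trained on all actives, one
on the potent subset), candidates are gated on the estimated class
probability under both models simultaneously, the gated set is partitioned
into diversity clusters with a deterministic max-min procedure on
1 - Tanimoto distance over radius-3 circular fingerprints, one
representative per non-singleton cluster is shortlisted, and structural
novelty of confirmed hits is quantified as the maximum Tanimoto similarity
to any training active on radius-2 fingerprints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BayesModel
from .chem_io import (
    Featurizer,
    MoleculeRecord,
    MoleculeSet,
    Rejection,
    circular_fingerprint,
    physchem_descriptors,
)

GATE_ACTIVE = "predicted_active"
GATE_INACTIVE = "predicted_inactive"
GATE_NEITHER = "neither"


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """|a & b| / |a | b|; two empty sets are defined as identical (1.0)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class ScreenRecord:
    """Per-library-compound screening result under both models."""

    id: str
    score_a: float
    score_b: float
    est_p_good_a: float
    est_p_good_b: float
    gate: str = GATE_NEITHER
    is_training: bool = False
    cluster_id: int | None = None
    selected: bool = False
    max_sim_to_training_actives: float | None = None
    mw: float | None = None

    @property
    def combined(self) -> float:
        return self.est_p_good_a + self.est_p_good_b

    @property
    def mean_est_p_good(self) -> float:
        return self.combined / 2.0


@dataclass
class ClusterAssignment:
    cluster_id: int
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def screen_library(
    model_a: BayesModel,
    model_b: BayesModel,
    library: MoleculeSet,
    training_ids: Iterable[str] = (),
) -> tuple[list[ScreenRecord], list[Rejection]]:
    """Score every library compound under both models.

    Returns records ranked by descending combined EstPGood (ties broken by
    id) plus per-compound featurization rejections.  Both models must share
    the fingerprint radius so their scores live in one feature space.
    """
    if model_a.featurizer.radius != model_b.featurizer.radius:
        raise ValueError("models must share the same fingerprint radius")
    training = set(training_ids)
    if len(library) == 0:
        warnings.warn("screening an empty library", stacklevel=2)
        return [], []
    records, rejections = [], []
    for rec in library.records:
        try:
            pred_a = model_a.predict(rec)
            pred_b = model_b.predict(rec)
            mw = physchem_descriptors(rec).mw
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            rejections.append(Rejection(rec.id, str(exc)))
            continue
        records.append(
            ScreenRecord(
                id=rec.id,
                score_a=pred_a.normalized_score,
                score_b=pred_b.normalized_score,
                est_p_good_a=pred_a.est_p_good,
                est_p_good_b=pred_b.est_p_good,
                is_training=rec.id in training,
                mw=mw,
            )
        )
    records.sort(key=lambda r: (-r.combined, r.id))
    return records, rejections


def gate_candidates(
    records: Sequence[ScreenRecord], hi: float = 0.9, lo: float = 0.1
) -> tuple[list[ScreenRecord], list[ScreenRecord]]:
    """Dual-model probability gate with strict inequalities.

    predicted_active iff EstPGood > hi under both models; predicted_inactive
    iff EstPGood < lo under both; everything else is left ungated.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    actives, inactives = [], []
    for r in records:
        if r.est_p_good_a > hi and r.est_p_good_b > hi:
            r.gate = GATE_ACTIVE
            actives.append(r)
        elif r.est_p_good_a < lo and r.est_p_good_b < lo:
            r.gate = GATE_INACTIVE
            inactives.append(r)
        else:
            r.gate = GATE_NEITHER
    return actives, inactives


def n_clusters_for(n: int, average_size: int) -> int:
    """Round-half-up of n / average_size, minimum 1."""
    import math

    return max(1, int(math.floor(n / average_size + 0.5)))


def cluster_partition(
    records: Sequence[ScreenRecord],
    fingerprints: Mapping[str, frozenset[int]],
    average_size: int = 5,
    n_clusters: int | None = None,
) -> list[ClusterAssignment]:
    """Partition a gated subset into diversity clusters.

    The number of clusters defaults to round(N / average_size).  Centroids
    are picked by deterministic max-min selection on distance 1 - Tanimoto:
    the first centroid is the compound with highest combined EstPGood (ties
    by id), each subsequent centroid maximizes its minimum distance to the
    centroids chosen so far (ties by id).  Every compound then joins its
    nearest centroid, ties going to the lower cluster id.
    """
    if not records:
        raise ValueError("cannot cluster an empty subset")
    k = n_clusters if n_clusters is not None else n_clusters_for(len(records), average_size)
    k = min(k, len(records))
    ordered = sorted(records, key=lambda r: (-r.combined, r.id))
    fps = {r.id: fingerprints[r.id] for r in records}

    centroid_ids = [ordered[0].id]
    remaining = [r.id for r in sorted(records, key=lambda r: r.id) if r.id != centroid_ids[0]]
    min_dist = {rid: 1.0 - tanimoto(fps[rid], fps[centroid_ids[0]]) for rid in remaining}
    while len(centroid_ids) < k:
        best_d = max(min_dist[rid] for rid in remaining)
        # among equally distant candidates take the lexicographically lowest id
        best = min(rid for rid in remaining if min_dist[rid] == best_d)
        centroid_ids.append(best)
        remaining.remove(best)
        for rid in remaining:
            d = 1.0 - tanimoto(fps[rid], fps[best])
            if d < min_dist[rid]:
                min_dist[rid] = d

    clusters = [ClusterAssignment(cluster_id=i, centroid_id=cid) for i, cid in enumerate(centroid_ids)]
    by_id = {r.id: r for r in records}
    for rid in sorted(by_id):
        dists = [1.0 - tanimoto(fps[rid], fps[c.centroid_id]) for c in clusters]
        ci = int(np.argmin(dists))  # argmin takes the first (lowest cluster_id) on ties
        clusters[ci].member_ids.append(rid)
        by_id[rid].cluster_id = ci
    return clusters


def select_representatives(
    clusters: Sequence[ClusterAssignment],
    records: Sequence[ScreenRecord],
    mw_range: tuple[float, float] | None = None,
) -> list[str]:
    """Shortlist one representative per non-singleton cluster.

    The pick is the non-training member with the highest mean EstPGood (ties
    by id), optionally restricted to a molecular-weight window.  Singleton
    clusters yield no selection; a cluster whose members are all training
    compounds (or all outside the window) triggers a warning and no pick.
    """
    by_id = {r.id: r for r in records}
    selected = []
    for cluster in clusters:
        if cluster.size < 2:
            continue
        candidates = [by_id[m] for m in cluster.member_ids if not by_id[m].is_training]
        if mw_range is not None:
            lo, hi = mw_range
            candidates = [c for c in candidates if c.mw is not None and lo <= c.mw <= hi]
        if not candidates:
            warnings.warn(
                f"cluster {cluster.cluster_id}: no selectable (non-training) member",
                stacklevel=2,
            )
            continue
        pick = min(candidates, key=lambda r: (-r.mean_est_p_good, r.id))
        pick.selected = True
        selected.append(pick.id)
    return selected


def max_pairwise_similarity(
    novel: MoleculeSet,
    training_actives: MoleculeSet,
    radius: int = 2,
) -> tuple[dict[str, float], np.ndarray]:
    """Per-compound maximum Tanimoto similarity to any training active.

    Computed on radius-2 circular fingerprints.  Also returns a 10-bin
    histogram over [0, 0.1), ..., [0.9, 1.0] (the last bin closed so that
    exact matches land in it).
    """
    if len(novel) == 0 or len(training_actives) == 0:
        raise ValueError("both molecule sets must be non-empty")
    train_fps = [circular_fingerprint(r, radius) for r in training_actives.records]
    sims: dict[str, float] = {}
    for rec in novel.records:
        fp = circular_fingerprint(rec, radius)
        sims[rec.id] = max(tanimoto(fp, t) for t in train_fps)
    hist, _ = np.histogram(list(sims.values()), bins=np.linspace(0.0, 1.0, 11))
    return sims, hist


def screen_table(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """Flat table of screening results (one row per library compound)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "score_A": [r.score_a for r in records],
            "score_B": [r.score_b for r in records],
            "estpgood_A": [r.est_p_good_a for r in records],
            "estpgood_B": [r.est_p_good_b for r in records],
            "gate": [r.gate for r in records],
            "is_training": [r.is_training for r in records],
            "cluster_id": [r.cluster_id for r in records],
            "selected": [r.selected for r in records],
            "max_sim": [r.max_sim_to_training_actives for r in records],
            "mw": [r.mw for r in records],
        }
    )


def run_screen(
    model_a: BayesModel,
    model_b: BayesModel,
    library: MoleculeSet,
    training_ids: Iterable[str] = (),
    hi: float = 0.9,
    lo: float = 0.1,
    average_size: int = 5,
    n_clusters: int | None = None,
    cluster_radius: int = 3,
) -> tuple[list[ScreenRecord], list[ClusterAssignment], list[str]]:
    """Screen -> gate -> cluster -> select, end to end, deterministically."""
    records, _ = screen_library(model_a, model_b, library, training_ids)
    gated, _ = gate_candidates(records, hi=hi, lo=lo)
    if not gated:
        return records, [], []
    by_id = {r.id: r for r in library.records}
    fps = {r.id: circular_fingerprint(by_id[r.id], cluster_radius) for r in gated}
    clusters = cluster_partition(gated, fps, average_size=average_size, n_clusters=n_clusters)
    selected = select_representatives(clusters, gated)
    return records, clusters, selected
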