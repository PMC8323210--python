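"""Snowballing propagation of similarity scores to unlabeled pair samples.

With the metric C fixed, each round finds, for every unlabeled pair sample,
its nearest labeled sample under the Mahalanobis distance; the batch of
unlabeled samples closest to the labeled set copy their nearest neighbor's
score and join the labeled set, which then serves the next round.  Labels are
copied, never interpolated, so the final score values are a subset of the
initial expert scores.  The process runs ceil(n_unlabeled / batch_size)
rounds and is fully deterministic (ties broken by canonical pair order).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = ["SnowballPropagator", "default_batch_size", "propagate_scores"]


def default_batch_size(n_unlabeled: int) -> int:
    """Default batch size: 0.15% of the unlabeled samples (half-up rounding),
    never below 1.  For the original study's 698,718 unlabeled pairs this rule
    gives 1048; the literal batch size used there (1153) can be passed as an
    explicit override."""
    if n_unlabeled < 1:
        raise ValueError("n_unlabeled must be >= 1")
    return max(1, int(math.floor(0.0015 * n_unlabeled + 0.5)))


def _metric_factor(C: np.ndarray) -> np.ndarray:
    """Factor a PSD metric C = L Lᵀ so Mahalanobis distance equals Euclidean
    distance on the L-projected coordinates."""
    C = np.asarray(C, dtype=float)
    w, U = eigh((C + C.T) / 2)
    w = np.clip(w, 0.0, None)
    keep = w > 1e-12 * max(w.max(), 1.0)
    return U[:, keep] * np.sqrt(w[keep])


class SnowballPropagator(BaseEstimator):
    """Semi-supervised snowball labeling of pair samples.

    ``fit(X, y)`` takes all pair vectors ``X`` (n_pairs, d) and a score array
    ``y`` with NaN marking unlabeled pairs; after fitting, ``scores_`` holds a
    score in [0, 1] for every pair and ``provenance_`` records, for each
    propagated pair, the labeled sample it copied from and the round number
    (round 0 = initially labeled).

    Parameters
    ----------
    metric : (d, d) PSD matrix C, or None for the identity (plain Euclidean).
    batch_size : int, or "auto" for the 0.15% rule of
        :func:`default_batch_size`.
    """

    def __init__(self, metric=None, batch_size="auto"):
        self.metric = metric
        self.batch_size = batch_size

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pairs, d) aligned with y")
        labeled = np.flatnonzero(~np.isnan(y))
        unlabeled = np.flatnonzero(np.isnan(y))
        if labeled.size == 0:
            raise ValueError("propagation needs at least one labeled sample")
        bad = y[labeled][(y[labeled] < 0) | (y[labeled] > 1)]
        if bad.size:
            raise ValueError(f"labeled scores must lie in [0, 1], got {bad[:3]}")

        coords = X if self.metric is None else X @ _metric_factor(self.metric)

        scores = y.copy()
        source = np.full(X.shape[0], -1, dtype=int)
        round_of = np.zeros(X.shape[0], dtype=int)
        n_rounds = 0

        if unlabeled.size:
            if self.batch_size == "auto":
                bsize = default_batch_size(unlabeled.size)
            else:
                bsize = int(self.batch_size)
                if bsize < 1:
                    raise ValueError("batch_size must be >= 1")
            # nearest initially-labeled neighbor for every unlabeled sample
            d0 = cdist(coords[unlabeled], coords[labeled])
            nearest_pos = d0.argmin(axis=1)
            nearest_dist = d0[np.arange(unlabeled.size), nearest_pos]
            nearest_idx = labeled[nearest_pos]

            remaining = np.arange(unlabeled.size)
            while remaining.size:
                n_rounds += 1
                # most confident first; ties by canonical pair order
                order = np.lexsort((unlabeled[remaining], nearest_dist[remaining]))
                batch = remaining[order[:bsize]]
                batch_idx = unlabeled[batch]
                scores[batch_idx] = scores[nearest_idx[batch]]
                source[batch_idx] = nearest_idx[batch]
                round_of[batch_idx] = n_rounds
                remaining = remaining[~np.isin(remaining, batch)]
                if remaining.size:
                    d_new = cdist(coords[unlabeled[remaining]], coords[batch_idx])
                    new_pos = d_new.argmin(axis=1)
                    new_dist = d_new[np.arange(remaining.size), new_pos]
                    closer = new_dist < nearest_dist[remaining]
                    upd = remaining[closer]
                    nearest_dist[upd] = new_dist[closer]
                    nearest_idx[upd] = batch_idx[new_pos[closer]]

        self.scores_ = scores
        self.n_rounds_ = n_rounds
        self.batch_size_ = (default_batch_size(unlabeled.size)
                            if (self.batch_size == "auto" and unlabeled.size)
                            else (self.batch_size if unlabeled.size else 0))
        self.provenance_ = pd.DataFrame({
            "index": np.arange(X.shape[0]),
            "source": source,
            "round": round_of,
        })
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).scores_


def propagate_scores(pair_table: pd.DataFrame, labeled_scores: dict,
                     metric=None, batch_size="auto") -> pd.DataFrame:
    """Functional wrapper over :class:`SnowballPropagator` for a pair table.

    ``pair_table`` is the output of
    :func:`emrsim.similarity.pairwise_similarity_table`; ``labeled_scores``
    maps canonical pair keys ``(id_a, id_b)`` to expert scores.  Returns the
    table with ``score``, ``source_pair`` and ``round`` columns appended.
    """
    V = pair_table[[f"v{i}" for i in range(1, 13)]].to_numpy()
    keys = list(zip(pair_table["id_a"], pair_table["id_b"]))
    y = np.full(len(keys), np.nan)
    seen = set()
    for k, key in enumerate(keys):
        if key in labeled_scores:
            y[k] = labeled_scores[key]
            seen.add(key)
    missing = set(labeled_scores) - seen
    if missing:
        raise ValueError(f"labeled pairs not present in the pair table: "
                         f"{sorted(missing)[:3]}")
    prop = SnowballPropagator(metric=metric, batch_size=batch_size).fit(V, y)
    out = pair_table.copy()
    out["score"] = prop.scores_
    src = prop.provenance_["source"].to_numpy()
    out["source_pair"] = [
        f"{keys[s][0]}|{keys[s][1]}" if s >= 0 else "" for s in src
    ]
    out["round"] = prop.provenance_["round"].to_numpy()
    return out
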