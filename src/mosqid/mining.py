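"""Distances, the triplet-margin loss, and the five tuple-mining strategies.

Deep metric learning trains an embedding so that same-class images sit close
and different-class images sit far. The loss for a mined triplet (anchor a,
positive p, negative n) is the hinge

    L = [ d_ap - d_an + m ]_+                     (margin m, default 0.1)

and a *miner* decides which of the O(n^3) candidate triplets (or O(n^2)
pairs) in a batch are informative enough to contribute. Five miners are
implemented, matching the reference metric-learning semantics:

* ``triplet_margin`` — margin-violating triplets, d_ap - d_an + m > 0;
* ``multi_similarity`` — pairs within epsilon of the hardest opposing pair
  (cosine similarity, epsilon default 0.1);
* ``pair_margin`` — positive pairs farther than ``pos_margin``, negative
  pairs closer than ``neg_margin`` (Euclidean);
* ``angular`` — triplets whose angular separation
  alpha = atan(d_ap / (2 d_nc)) exceeds a threshold, where d_nc is the
  distance from the negative to the anchor-positive midpoint;
* ``distance_weighted`` — one negative per anchor sampled with probability
  inversely proportional to the unit-sphere distance density
  q(d) ~ d^(D-2) (1 - d^2/4)^((D-3)/2).

Batches come from an M-per-class sampler (batch 16, m = 8 by default), which
guarantees every anchor has positives. A two-stage architecture lets an
optional subset-batch stage shrink the batch before any tuple miner runs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DistanceMatrix", "TripletSet", "PairSet", "MinerConfig",
    "pairwise_distances", "triplet_margin_loss", "mine_triplet_margin",
    "mine_multi_similarity", "mine_pair_margin", "mine_angular",
    "mine_distance_weighted", "mine", "pairs_to_triplets",
    "m_per_class_sample_batches", "two_stage_mine", "identity_subset_stage",
]

MINER_KINDS = ("angular", "distance_weighted", "multi_similarity",
               "pair_margin", "triplet_margin")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric: str  # {"euclidean", "cosine"}


@dataclass
class TripletSet:
    """(anchor, positive, negative) index triples into the mined batch."""

    triplets: np.ndarray  # (k, 3) int

    def __post_init__(self):
        self.triplets = np.asarray(self.triplets, dtype=np.intp).reshape(-1, 3)

    def __len__(self):
        return len(self.triplets)

    @property
    def anchors(self):
        return self.triplets[:, 0]

    @property
    def positives(self):
        return self.triplets[:, 1]

    @property
    def negatives(self):
        return self.triplets[:, 2]


@dataclass
class PairSet:
    positive_pairs: np.ndarray  # (k, 2) int, same label, ordered, no self
    negative_pairs: np.ndarray  # (k, 2) int, different label

    def __post_init__(self):
        self.positive_pairs = np.asarray(self.positive_pairs,
                                         dtype=np.intp).reshape(-1, 2)
        self.negative_pairs = np.asarray(self.negative_pairs,
                                         dtype=np.intp).reshape(-1, 2)

    def __len__(self):
        return len(self.positive_pairs) + len(self.negative_pairs)


@dataclass
class MinerConfig:
    kind: str = "multi_similarity"
    epsilon: float = 0.1            # multi_similarity
    margin: float = 0.1             # triplet_margin
    pos_margin: float = 0.2         # pair_margin
    neg_margin: float = 0.8         # pair_margin
    angle_threshold: float = 20.0   # angular, degrees
    cutoff: float = 0.5             # distance_weighted lower clamp
    nonzero_loss_cutoff: float = 1.4  # distance_weighted upper clamp

    def __post_init__(self):
        if self.kind not in MINER_KINDS:
            raise ValueError(f"unknown miner kind {self.kind!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for name in ("margin", "pos_margin", "neg_margin", "angle_threshold",
                     "cutoff", "nonzero_loss_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MinerConfig":
        return cls(**d)


# ------------------------------------------------------------------ distances

def pairwise_distances(embeddings: np.ndarray,
                       metric: str = "euclidean") -> DistanceMatrix:
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim != 2 or len(x) < 1:
        raise ValueError("embeddings must be a nonempty (n, d) array")
    if metric == "euclidean":
        vals = cdist(x, x, metric="euclidean")
        np.fill_diagonal(vals, 0.0)
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms == 0):
            raise ValueError("cosine similarity undefined for zero vectors")
        vals = (x @ x.T) / np.outer(norms, norms)
        vals = np.clip(vals, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=vals, metric=metric)


def triplet_margin_loss(d_ap, d_an, m: float = 0.1) -> float:
    """Hinge loss ``max(d_ap - d_an + m, 0)``; arrays give the batch mean.

    An empty batch contributes zero loss so training proceeds when a miner
    returns nothing.
    """
    d_ap = np.asarray(d_ap, dtype=np.float64)
    d_an = np.asarray(d_an, dtype=np.float64)
    if np.any(d_ap < 0) or np.any(d_an < 0):
        raise ValueError("distances must be nonnegative")
    if m < 0:
        raise ValueError("margin must be nonnegative")
    if d_ap.size == 0:
        return 0.0
    return float(np.mean(np.maximum(d_ap - d_an + m, 0.0)))


# --------------------------------------------------------------------- miners

def _label_masks(labels):
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return labels, same


def _check_two_labels(labels):
    if len(np.unique(np.asarray(labels))) < 2:
        return False
    return True


def mine_triplet_margin(embeddings, labels,
                        config: MinerConfig | None = None) -> TripletSet:
    """All valid triplets violating the margin: d_ap - d_an + m > 0."""
    config = config or MinerConfig(kind="triplet_margin")
    labels, same = _label_masks(labels)
    n = len(labels)
    if not _check_two_labels(labels):
        return TripletSet(np.empty((0, 3)))
    D = pairwise_distances(embeddings).values
    viol = D[:, :, None] - D[:, None, :] + config.margin > 0   # [a, p, n]
    valid = (same[:, :, None] & ~np.eye(n, dtype=bool)[:, :, None]
             & ~same[:, None, :])
    a, p, ng = np.nonzero(viol & valid)
    return TripletSet(np.stack([a, p, ng], axis=1))


def mine_multi_similarity(embeddings, labels, epsilon: float = 0.1) -> PairSet:
    """Keep pairs within epsilon of the hardest opposing pair (cosine).

    For anchor a: positive (a, p) survives iff sim(a, p) < max_n sim(a, n)
    + epsilon; negative (a, n) survives iff sim(a, n) > min_p sim(a, p)
    - epsilon.
    """
    labels, same = _label_masks(labels)
    n = len(labels)
    S = pairwise_distances(embeddings, metric="cosine").values
    eye = np.eye(n, dtype=bool)
    pos_mask = same & ~eye
    neg_mask = ~same
    hardest_neg = np.where(neg_mask.any(axis=1),
                           np.max(np.where(neg_mask, S, -np.inf), axis=1),
                           -np.inf)
    hardest_pos = np.where(pos_mask.any(axis=1),
                           np.min(np.where(pos_mask, S, np.inf), axis=1),
                           np.inf)
    keep_pos = pos_mask & (S < hardest_neg[:, None] + epsilon)
    keep_neg = neg_mask & (S > hardest_pos[:, None] - epsilon)
    pa, pp = np.nonzero(keep_pos)
    na, nn = np.nonzero(keep_neg)
    return PairSet(np.stack([pa, pp], axis=1), np.stack([na, nn], axis=1))


def mine_pair_margin(embeddings, labels, pos_margin: float = 0.2,
                     neg_margin: float = 0.8) -> PairSet:
    """Positive pairs farther than pos_margin, negatives closer than
    neg_margin (Euclidean)."""
    labels, same = _label_masks(labels)
    n = len(labels)
    D = pairwise_distances(embeddings).values
    eye = np.eye(n, dtype=bool)
    keep_pos = same & ~eye & (D > pos_margin)
    keep_neg = ~same & (D < neg_margin)
    pa, pp = np.nonzero(keep_pos)
    na, nn = np.nonzero(keep_neg)
    return PairSet(np.stack([pa, pp], axis=1), np.stack([na, nn], axis=1))


def mine_angular(embeddings, labels, angle_threshold: float = 20.0) -> TripletSet:
    """Triplets with angular separation atan(d_ap / (2 d_nc)) > threshold.

    d_nc is the distance from the negative to the anchor-positive midpoint.
    Triplets whose anchor and positive coincide are skipped as degenerate.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    labels, same = _label_masks(labels)
    n = len(labels)
    if not _check_two_labels(labels):
        return TripletSet(np.empty((0, 3)))
    D = pairwise_distances(x).values
    valid = (same[:, :, None] & ~np.eye(n, dtype=bool)[:, :, None]
             & ~same[:, None, :])
    a, p, ng = np.nonzero(valid)
    d_ap = D[a, p]
    nondeg = d_ap > 0
    a, p, ng, d_ap = a[nondeg], p[nondeg], ng[nondeg], d_ap[nondeg]
    centroid = (x[a] + x[p]) / 2.0
    d_nc = np.linalg.norm(x[ng] - centroid, axis=1)
    with np.errstate(divide="ignore"):
        alpha = np.arctan(np.where(d_nc > 0, d_ap / (2.0 * np.maximum(d_nc, 1e-300)),
                                   np.inf))
    keep = alpha > np.deg2rad(angle_threshold)
    return TripletSet(np.stack([a[keep], p[keep], ng[keep]], axis=1))


def _inverse_density_log_weight(d: np.ndarray, dim: int) -> np.ndarray:
    # log 1/q(d) with q(d) ~ d^(D-2) (1 - d^2/4)^((D-3)/2) on the unit sphere
    return -((dim - 2) * np.log(d) + 0.5 * (dim - 3) * np.log(1.0 - d * d / 4.0))


def mine_distance_weighted(embeddings, labels, cutoff: float = 0.5,
                           nonzero_loss_cutoff: float = 1.4,
                           seed: int = 0) -> TripletSet:
    """Per anchor, sample one negative inversely to the sphere distance
    density; positives are all same-label partners. Requires unit-norm
    embeddings.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("distance-weighted mining requires L2-normalized "
                         "embeddings")
    labels, same = _label_masks(labels)
    n = len(labels)
    D = pairwise_distances(x).values
    rng = np.random.default_rng(seed)
    triplets = []
    dim = x.shape[1]
    for a in range(n):
        pos = np.nonzero(same[a] & (np.arange(n) != a))[0]
        neg = np.nonzero(~same[a])[0]
        if len(pos) == 0 or len(neg) == 0:
            continue
        d = np.clip(D[a, neg], cutoff, nonzero_loss_cutoff)
        logw = _inverse_density_log_weight(d, dim)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        chosen = neg[rng.choice(len(neg), p=w)]
        for p in pos:
            triplets.append((a, p, chosen))
    if not triplets:
        return TripletSet(np.empty((0, 3)))
    return TripletSet(np.asarray(triplets))


def mine(embeddings, labels, config: MinerConfig,
         seed: int = 0) -> TripletSet | PairSet:
    """Dispatch to the configured miner."""
    if config.kind == "triplet_margin":
        return mine_triplet_margin(embeddings, labels, config)
    if config.kind == "multi_similarity":
        return mine_multi_similarity(embeddings, labels, config.epsilon)
    if config.kind == "pair_margin":
        return mine_pair_margin(embeddings, labels, config.pos_margin,
                                config.neg_margin)
    if config.kind == "angular":
        return mine_angular(embeddings, labels, config.angle_threshold)
    if config.kind == "distance_weighted":
        return mine_distance_weighted(embeddings, labels, config.cutoff,
                                      config.nonzero_loss_cutoff, seed)
    raise ValueError(f"unknown miner kind {config.kind!r}")


def pairs_to_triplets(pairs: PairSet) -> TripletSet:
    """Join positive and negative pairs sharing an anchor into triplets.

    Pair-based miners feed the triplet-margin loss through this conversion:
    every (a, p) is combined with every (a, n) of the same anchor.
    """
    triplets = []
    pos_by_anchor: dict[int, list[int]] = {}
    for a, p in pairs.positive_pairs:
        pos_by_anchor.setdefault(int(a), []).append(int(p))
    for a, n in pairs.negative_pairs:
        for p in pos_by_anchor.get(int(a), ()):
            triplets.append((int(a), p, int(n)))
    if not triplets:
        return TripletSet(np.empty((0, 3)))
    return TripletSet(np.asarray(triplets))


# ------------------------------------------------------------------- sampling

def m_per_class_sample_batches(labels, batch_size: int = 16, m: int = 8,
                               seed: int = 0,
                               n_batches: int | None = None) -> list[np.ndarray]:
    """Episodic batches: batch_size/m distinct classes, m samples each.

    Classes with fewer than m images are sampled with replacement. The batch
    sequence is a pure function of (labels, batch_size, m, seed).
    """
    labels = np.asarray(labels)
    if batch_size % m != 0:
        raise ValueError(f"batch_size {batch_size} not divisible by m {m}")
    classes = np.unique(labels)
    per_batch = batch_size // m
    if len(classes) < per_batch:
        raise ValueError(f"need at least {per_batch} classes, got {len(classes)}")
    if n_batches is None:
        n_batches = max(1, int(np.ceil(len(labels) / batch_size)))
    idx_by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    rng = np.random.default_rng(seed)
    batches = []
    for _ in range(n_batches):
        chosen = rng.choice(classes, size=per_batch, replace=False)
        batch = []
        for c in chosen:
            pool = idx_by_class[c]
            take = rng.choice(pool, size=m, replace=len(pool) < m)
            batch.append(take)
        batches.append(np.concatenate(batch))
    return batches


# ------------------------------------------------------------------ two-stage

def identity_subset_stage(embeddings, labels) -> np.ndarray:
    return np.arange(len(labels))


def two_stage_mine(embeddings, labels, config: MinerConfig,
                   subset_stage=None, seed: int = 0):
    """Subset-batch stage then tuple miner; indices map back to the full batch.

    With the identity subset stage this reproduces the plain miner output.
    """
    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels)
    stage = subset_stage or identity_subset_stage
    idx = np.asarray(stage(embeddings, labels), dtype=np.intp)
    out = mine(embeddings[idx], labels[idx], config, seed=seed)
    if isinstance(out, TripletSet):
        return TripletSet(idx[out.triplets])
    return PairSet(idx[out.positive_pairs] if len(out.positive_pairs) else
                   np.empty((0, 2)),
                   idx[out.negative_pairs] if len(out.negative_pairs) else
                   np.empty((0, 2)))
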