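"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops straight from the selection-rule
definitions, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_distance_matrix(x: np.ndarray) -> np.ndarray:
    n = len(x)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.sqrt(sum((x[i, d] - x[j, d]) ** 2
                                      for d in range(x.shape[1])))
    return out


def brute_cosine_matrix(x: np.ndarray) -> np.ndarray:
    n = len(x)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(x[i, d] * x[j, d] for d in range(x.shape[1]))
            ni = math.sqrt(sum(v * v for v in x[i]))
            nj = math.sqrt(sum(v * v for v in x[j]))
            out[i, j] = num / (ni * nj)
    return out


def _dist(a, b):
    return math.sqrt(float(np.sum((np.asarray(a) - np.asarray(b)) ** 2)))


def brute_triplet_margin_miner(x, labels, margin):
    n = len(labels)
    out = set()
    for a in range(n):
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            for ng in range(n):
                if labels[ng] == labels[a]:
                    continue
                if _dist(x[a], x[p]) - _dist(x[a], x[ng]) + margin > 0:
                    out.add((a, p, ng))
    return out


def brute_triplet_loss_mean(x, labels, margin):
    """Mean hinge loss over every valid (not only violating) triplet."""
    vals = []
    n = len(labels)
    for a in range(n):
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            for ng in range(n):
                if labels[ng] == labels[a]:
                    continue
                vals.append(max(_dist(x[a], x[p]) - _dist(x[a], x[ng]) + margin,
                                0.0))
    return float(np.mean(vals)) if vals else 0.0


def brute_multi_similarity_miner(x, labels, epsilon):
    n = len(labels)
    S = brute_cosine_matrix(np.asarray(x, dtype=float))
    pos_kept, neg_kept = set(), set()
    for a in range(n):
        negs = [j for j in range(n) if labels[j] != labels[a]]
        poss = [j for j in range(n) if j != a and labels[j] == labels[a]]
        if negs and poss:
            hardest_neg = max(S[a, j] for j in negs)
            hardest_pos = min(S[a, j] for j in poss)
            for p in poss:
                if S[a, p] < hardest_neg + epsilon:
                    pos_kept.add((a, p))
            for ng in negs:
                if S[a, ng] > hardest_pos - epsilon:
                    neg_kept.add((a, ng))
    return pos_kept, neg_kept


def brute_pair_margin_miner(x, labels, pos_margin, neg_margin):
    n = len(labels)
    pos_kept, neg_kept = set(), set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = _dist(x[i], x[j])
            if labels[i] == labels[j] and d > pos_margin:
                pos_kept.add((i, j))
            if labels[i] != labels[j] and d < neg_margin:
                neg_kept.add((i, j))
    return pos_kept, neg_kept


def brute_angular_miner(x, labels, threshold_deg):
    n = len(labels)
    out = set()
    for a in range(n):
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            d_ap = _dist(x[a], x[p])
            if d_ap == 0:
                continue
            for ng in range(n):
                if labels[ng] == labels[a]:
                    continue
                c = (np.asarray(x[a], dtype=float)
                     + np.asarray(x[p], dtype=float)) / 2.0
                d_nc = _dist(x[ng], c)
                alpha = math.atan(d_ap / (2 * d_nc)) if d_nc > 0 \
                    else math.pi / 2
                if alpha > math.radians(threshold_deg):
                    out.add((a, p, ng))
    return out


def inverse_density_weight(d: float, dim: int) -> float:
    """1 / q(d) for the unit-sphere pairwise-distance density."""
    q = d ** (dim - 2) * (1.0 - d * d / 4.0) ** ((dim - 3) / 2.0)
    return 1.0 / q


def lloyd_kmeans(x: np.ndarray, centers: np.ndarray,
                 iters: int = 100) -> np.ndarray:
    """Plain Lloyd iteration from given initial centers."""
    centers = centers.copy().astype(float)
    assign = np.zeros(len(x), dtype=int)
    for _ in range(iters):
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for c in range(len(centers)):
            members = x[assign == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    return assign


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """Tie-corrected rank-statistic AUC."""
    wins = 0.0
    for s1 in pos_scores:
        for s0 in neg_scores:
            if s1 > s0:
                wins += 1.0
            elif s1 == s0:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
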