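"""Content-based image retrieval: gallery index, kNN voting, gallery extension.

At inference a query image is embedded and the k = 20 nearest gallery
embeddings (Euclidean distance, ascending) are retrieved. A cosine-similarity
match filter (threshold 0.5) then discards neighbours too dissimilar to
count; if none survive, the query is reported as a no-match rather than
forced into a class. The surviving neighbours vote: each class scores
100 * count / survivors percent and the highest score wins, with ties broken
by smaller mean neighbour distance, then lexicographic class code.

The gallery can be *extended* with pseudo-training images — newly labelled
references, possibly from classes or sources never seen in training — with
zero retraining: their embeddings are simply appended under a
``pseudo_train`` provenance flag, and the model parameters are untouched.

Because embeddings are unit-norm, Euclidean and descending-cosine orderings
agree; search is exhaustive, which is exact at this gallery scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import DatasetManifest, ImageRecord, load_record_image
from .embednet import EmbeddingModel, embed_images

__all__ = [
    "EmbeddingIndex", "RetrievalResult", "build_index", "extend_index",
    "retrieve", "match_filter", "vote_classify", "predict_batch",
    "save_index", "load_index",
]


@dataclass
class EmbeddingIndex:
    embeddings: np.ndarray          # (n, d) unit-norm
    labels: np.ndarray              # class codes
    image_ids: np.ndarray
    provenance: np.ndarray          # {"trained", "pseudo_train"}

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.image_ids = np.asarray(self.image_ids)
        self.provenance = np.asarray(self.provenance)
        n = len(self.embeddings)
        if n < 1:
            raise ValueError("index must contain at least one embedding")
        if not (len(self.labels) == len(self.image_ids)
                == len(self.provenance) == n):
            raise ValueError("index rows, labels, ids, provenance misaligned")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("index embeddings must be unit-norm")

    def __len__(self):
        return len(self.embeddings)


@dataclass
class Neighbour:
    image_id: str
    label: str
    distance: float          # Euclidean
    similarity: float        # cosine


@dataclass
class RetrievalResult:
    query_id: str
    neighbours: list[Neighbour]
    class_scores: dict[str, float]      # percentages over survivors
    predicted: str | None
    matched: bool


# -------------------------------------------------------------------- building

def build_index(model: EmbeddingModel, records: list[ImageRecord],
                provenance: str = "trained") -> EmbeddingIndex:
    """Embed one gallery row per record (eval-mode forward pass)."""
    if not records:
        raise ValueError("cannot build an index from zero records")
    res = model.config.input_resolution
    images = np.stack([load_record_image(r, res) for r in records])
    emb = embed_images(model, images)
    return EmbeddingIndex(
        embeddings=emb,
        labels=np.asarray([r.class_code for r in records]),
        image_ids=np.asarray([r.image_id for r in records]),
        provenance=np.asarray([provenance] * len(records)),
    )


def extend_index(index: EmbeddingIndex, model: EmbeddingModel,
                 pseudo_records: list[ImageRecord]) -> EmbeddingIndex:
    """Append pseudo-training rows; existing rows and model stay untouched."""
    if not pseudo_records:
        return EmbeddingIndex(index.embeddings.copy(), index.labels.copy(),
                              index.image_ids.copy(), index.provenance.copy())
    extra = build_index(model, pseudo_records, provenance="pseudo_train")
    if extra.embeddings.shape[1] != index.embeddings.shape[1]:
        raise ValueError("embedding dimension mismatch between index and model")
    return EmbeddingIndex(
        embeddings=np.vstack([index.embeddings, extra.embeddings]),
        labels=np.concatenate([index.labels, extra.labels]),
        image_ids=np.concatenate([index.image_ids, extra.image_ids]),
        provenance=np.concatenate([index.provenance, extra.provenance]),
    )


# ------------------------------------------------------------------- retrieval

def retrieve(index: EmbeddingIndex, query: np.ndarray,
             k: int = 20) -> list[Neighbour]:
    """The k nearest gallery rows by Euclidean distance, ascending.

    k larger than the gallery returns the whole gallery. Distance ties are
    broken by gallery order for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.shape[0] != index.embeddings.shape[1]:
        raise ValueError("query dimension mismatch")
    d = np.linalg.norm(index.embeddings - q, axis=1)
    sim = index.embeddings @ q / max(np.linalg.norm(q), 1e-300)
    order = np.argsort(d, kind="stable")[:min(k, len(index))]
    return [Neighbour(image_id=str(index.image_ids[i]),
                      label=str(index.labels[i]),
                      distance=float(d[i]), similarity=float(sim[i]))
            for i in order]


def match_filter(neighbours: list[Neighbour],
                 threshold: float = 0.5) -> tuple[list[Neighbour], bool]:
    """Drop neighbours with cosine similarity below the threshold.

    Returns (survivors, matched); matched is False when nothing survives.
    """
    kept = [nb for nb in neighbours if nb.similarity >= threshold]
    return kept, bool(kept)


def vote_classify(neighbours: list[Neighbour]) -> tuple[dict[str, float],
                                                        str | None]:
    """Percentage vote over the neighbour list.

    score(c) = 100 * count(c) / len(neighbours); the top score wins. Ties go
    to the class with the smaller mean neighbour distance, then to the
    lexicographically smaller code. An empty list signals no-match (None).
    """
    if not neighbours:
        return {}, None
    counts: dict[str, int] = {}
    dist_sum: dict[str, float] = {}
    for nb in neighbours:
        counts[nb.label] = counts.get(nb.label, 0) + 1
        dist_sum[nb.label] = dist_sum.get(nb.label, 0.0) + nb.distance
    total = len(neighbours)
    scores = {c: 100.0 * n / total for c, n in counts.items()}
    predicted = min(scores,
                    key=lambda c: (-scores[c], dist_sum[c] / counts[c], c))
    return scores, predicted


def predict_batch(model: EmbeddingModel, index: EmbeddingIndex,
                  images, query_ids=None, k: int = 20,
                  threshold: float = 0.5) -> list[RetrievalResult]:
    """embed -> retrieve -> match_filter -> vote_classify for each query.

    `images` must already be at the model input resolution (robustness
    queries are rescaled to 32x32 upstream).
    """
    emb = embed_images(model, images)
    if query_ids is None:
        query_ids = [f"q{i}" for i in range(len(emb))]
    results = []
    for qid, e in zip(query_ids, emb):
        neighbours = retrieve(index, e, k=k)
        survivors, matched = match_filter(neighbours, threshold=threshold)
        scores, predicted = vote_classify(survivors)
        results.append(RetrievalResult(query_id=str(qid), neighbours=survivors,
                                       class_scores=scores, predicted=predicted,
                                       matched=matched))
    return results


def predict_manifest(model: EmbeddingModel, index: EmbeddingIndex,
                     records: list[ImageRecord], k: int = 20,
                     threshold: float = 0.5) -> list[RetrievalResult]:
    """predict_batch over manifest records, loading images at model resolution."""
    res = model.config.input_resolution
    images = np.stack([load_record_image(r, res) for r in records])
    return predict_batch(model, index, images,
                         query_ids=[r.image_id for r in records],
                         k=k, threshold=threshold)


# ------------------------------------------------------------------- index I/O

def save_index(index: EmbeddingIndex, path: str | Path) -> None:
    """Array container (.npz) plus a JSON sidecar with ids/labels/provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, embeddings=index.embeddings)
    sidecar = {
        "image_ids": [str(i) for i in index.image_ids],
        "labels": [str(l) for l in index.labels],
        "provenance": [str(p) for p in index.provenance],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_index(path: str | Path) -> EmbeddingIndex:
    path = Path(path)
    data = np.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EmbeddingIndex(embeddings=data["embeddings"],
                          labels=np.asarray(sidecar["labels"]),
                          image_ids=np.asarray(sidecar["image_ids"]),
                          provenance=np.asarray(sidecar["provenance"]))


def results_to_frame(results: list[RetrievalResult]) -> pd.DataFrame:
    """Flatten retrieval results for the results CSV."""
    rows = []
    for r in results:
        rows.append({
            "query_id": r.query_id,
            "predicted": r.predicted if r.predicted is not None else "",
            "matched": r.matched,
            "neighbour_ids": "|".join(nb.image_id for nb in r.neighbours),
            "neighbour_labels": "|".join(nb.label for nb in r.neighbours),
            "neighbour_distances": "|".join(f"{nb.distance:.6f}"
                                            for nb in r.neighbours),
            "class_scores": "|".join(f"{c}:{s:.2f}"
                                     for c, s in sorted(r.class_scores.items())),
        })
    return pd.DataFrame(rows)
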