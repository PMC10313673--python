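"""Joint training loop: classification cross-entropy + mined triplet loss.

Each step draws an M-per-class batch (16 images, 8 per class by default),
embeds it, mines informative tuples, and minimises

    L = w_cls * CrossEntropy(logits, labels) + w_met * TripletMargin(mined)

with Adam (beta1 0.9, beta2 0.999, weight decay 0.001, eps 1e-8) at
per-part learning rates: 1e-5 for the backbone, 1e-4 for the embedder and
classifier. The default schedule is 200 epochs; the best epoch by
validation accuracy is retained. A k-means pass (k = 20) over the training
embeddings is logged each epoch as a cluster-purity monitor — it carries no
gradient and never feeds back into the loss.

Validation is carved from the train split (10%, stratified); the test split
never touches training.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .dataio import DatasetManifest, ImageRecord, load_record_image
from .embednet import EmbeddingModel, preprocess, save_checkpoint, load_checkpoint
from .mining import (MinerConfig, PairSet, TripletSet, mine,
                     m_per_class_sample_batches, pairs_to_triplets)
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig", "TrainHistory", "train_model", "evaluate_epoch",
    "kmeans_monitor", "cross_entropy_loss", "metric_loss",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.001
    adam_eps: float = 1e-8
    lr_backbone: float = 1e-5
    lr_embedder: float = 1e-4
    lr_classifier: float = 1e-4
    batch_size: int = 16
    m_per_class: int = 8
    margin: float = 0.1
    miner: MinerConfig = field(default_factory=MinerConfig)
    seed: int = 0
    w_classification: float = 1.0
    w_metric: float = 1.0
    batches_per_epoch: int | None = None
    val_fraction: float = 0.1
    kmeans_k: int = 20

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("lr_backbone", "lr_embedder", "lr_classifier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    purities: list[float] = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------- losses

def cross_entropy_loss(logits: Tensor, label_idx: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true classes."""
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), np.asarray(label_idx, dtype=np.intp)] = 1.0
    return -(logits.log_softmax() * Tensor(onehot)).sum() / float(n)


def metric_loss(embeddings: Tensor, mined: TripletSet | PairSet,
                margin: float = 0.1) -> Tensor:
    """Differentiable batch-mean triplet-margin loss over mined tuples.

    Pair-miner output is joined into triplets through shared anchors. An
    empty mining result contributes an exact zero.
    """
    triplets = pairs_to_triplets(mined) if isinstance(mined, PairSet) else mined
    if len(triplets) == 0:
        return Tensor(0.0)
    a = embeddings.take_rows(triplets.anchors)
    p = embeddings.take_rows(triplets.positives)
    n = embeddings.take_rows(triplets.negatives)
    d_ap = (((a - p) * (a - p)).sum(axis=1) + 1e-12).sqrt()
    d_an = (((a - n) * (a - n)).sum(axis=1) + 1e-12).sqrt()
    return (d_ap - d_an + margin).relu().mean()


# ------------------------------------------------------------------ monitoring

def evaluate_epoch(model: EmbeddingModel, images, label_idx) -> float:
    """Classifier-head accuracy: correct argmax predictions / n."""
    label_idx = np.asarray(label_idx)
    if len(label_idx) == 0:
        raise ValueError("validation set is empty")
    was_training = model.training
    model.eval()
    try:
        _, logits = model.forward(preprocess(images))
    finally:
        if was_training:
            model.train()
    pred = logits.data.argmax(axis=1)
    return float(np.mean(pred == label_idx))


def kmeans_monitor(embeddings: np.ndarray, labels, k: int = 20,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Seeded k-means over the embedding space plus cluster purity.

    Purity is the fraction of points that share their cluster's majority
    label. Degenerate inputs (fewer distinct points than k) are flagged with
    a warning; k-means still runs on the distinct points available.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if len(x) < k:
        raise ValueError(f"need at least k={k} points, got {len(x)}")
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k:
        warnings.warn(f"only {n_distinct} distinct embeddings for k={k}; "
                      "clusters are degenerate", stacklevel=2)
        k = max(1, n_distinct)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(x)
    purity = 0.0
    for c in range(k):
        members = labels[assign == c]
        if len(members):
            _, counts = np.unique(members, return_counts=True)
            purity += counts.max()
    return assign, purity / len(x)


# ------------------------------------------------------------------- training

def _carve_validation(records: list[ImageRecord], fraction: float,
                      seed: int) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Stratified validation carve-out from the train split."""
    by_class: dict[str, list[ImageRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_code, []).append(r)
    train, val = [], []
    for code, recs in sorted(by_class.items()):
        n_val = max(1, math.floor(len(recs) * fraction + 0.5))
        ranked = sorted(recs, key=lambda r: hashlib.sha256(
            f"val:{seed}:{r.image_id}".encode()).hexdigest())
        val.extend(ranked[:n_val])
        train.extend(ranked[n_val:])
    return train, val


def _epoch_seed(seed: int, epoch: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([seed, epoch, salt])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def train_model(model: EmbeddingModel, manifest: DatasetManifest,
                config: TrainConfig, checkpoint_path=None,
                verbose: bool = False) -> tuple[EmbeddingModel, TrainHistory]:
    """Train in place; returns the model restored to its best epoch.

    The best epoch maximises validation accuracy (ties: earliest epoch). If
    `checkpoint_path` is given the best weights are also written to disk.
    """
    train_records = manifest.subset("train")
    codes = sorted({r.class_code for r in train_records})
    if len(codes) < 2:
        raise ValueError("training requires at least 2 classes")
    if model.n_out < len(codes):
        raise ValueError(f"classifier width {model.n_out} < {len(codes)} classes")
    label_to_idx = {c: i for i, c in enumerate(codes)}
    if not model.vocabulary:
        model.vocabulary = codes

    fit_records, val_records = _carve_validation(
        train_records, config.val_fraction, config.seed)
    res = model.config.input_resolution
    cache = {r.image_id: load_record_image(r, res)
             for r in train_records}
    fit_images = np.stack([cache[r.image_id] for r in fit_records])
    fit_labels = np.asarray([label_to_idx[r.class_code] for r in fit_records])
    fit_codes = np.asarray([r.class_code for r in fit_records])
    val_images = np.stack([cache[r.image_id] for r in val_records])
    val_labels = np.asarray([label_to_idx[r.class_code] for r in val_records])

    optimizer = Adam(
        [{"params": g, "lr": lr} for g, lr in zip(
            model.parameter_groups().values(),
            (config.lr_backbone, config.lr_embedder, config.lr_classifier))],
        beta1=config.beta1, beta2=config.beta2, eps=config.adam_eps,
        weight_decay=config.weight_decay)

    history = TrainHistory()
    best_acc = -1.0
    best_state = None
    for epoch in range(config.epochs):
        model.train()
        batches = m_per_class_sample_batches(
            fit_codes, batch_size=config.batch_size, m=config.m_per_class,
            seed=_epoch_seed(config.seed, epoch),
            n_batches=config.batches_per_epoch)
        epoch_loss = 0.0
        for bi, batch in enumerate(batches):
            x = preprocess(fit_images[batch])
            x.requires_grad = False
            emb = model.embed(x)
            logits = model.logits(emb)
            cls_loss = cross_entropy_loss(logits, fit_labels[batch])
            mined = mine(emb.data, fit_codes[batch], config.miner,
                         seed=_epoch_seed(config.seed, epoch, salt=bi + 1))
            met_loss = metric_loss(emb, mined, margin=config.margin)
            loss = config.w_classification * cls_loss \
                + config.w_metric * met_loss
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}: "
                    f"cls={cls_loss.data}, metric={met_loss.data}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
        epoch_loss /= max(1, len(batches))

        val_acc = evaluate_epoch(model, val_images, val_labels)
        model.eval()
        train_emb = model.embed(preprocess(fit_images)).data
        k = min(config.kmeans_k, len(train_emb))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, purity = kmeans_monitor(train_emb, fit_codes, k=k,
                                       seed=_epoch_seed(config.seed, epoch, 999))
        history.losses.append(epoch_loss)
        history.val_accuracies.append(val_acc)
        history.purities.append(purity)
        if verbose:
            print(f"epoch={epoch} loss={epoch_loss:.4f} "
                  f"val_acc={val_acc:.4f} purity={purity:.4f}")
        if val_acc > best_acc:
            best_acc = val_acc
            history.best_epoch = epoch
            best_state = ([p.data.copy() for p in model.parameters()],
                          [b.copy() for _, b in model.buffers()])

    if best_state is not None:
        for p, saved in zip(model.parameters(), best_state[0]):
            p.data = saved
        for (_, b), saved in zip(model.buffers(), best_state[1]):
            b[...] = saved
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    model.eval()
    return model, history
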