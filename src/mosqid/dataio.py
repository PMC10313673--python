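"""Dataset model, manifest I/O and image preprocessing.

A specimen corpus is a :class:`DatasetManifest`: one :class:`ImageRecord` per
photographed insect plus a vocabulary of :class:`ClassLabel` entries (species
× sex class codes such as ``Adir_f`` for female *Anopheles dirus*, or ``mNM``
for the non-mosquito housefly control). Manifests round-trip through a CSV
(columns ``image_id,path,class_code,source,split[,x0,y0,x1,y1]``) with a JSON
sidecar holding the vocabulary and the split seed.

Images are handled as uint8 RGB arrays (H, W, 3). Bounding boxes are 0-based
half-open ``(x0, y0, x1, y1)`` pixel boxes with the origin at the top-left.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "ClassLabel", "ImageRecord", "DatasetManifest",
    "crop_to_bbox", "resize_image", "apply_gaussian_noise", "split_dataset",
    "read_manifest", "write_manifest", "load_image", "save_image", "infer_label",
]

SOURCES = ("stereo", "phone", "external")
SPLITS = ("train", "test", "pseudo_train")


@dataclass(frozen=True)
class ClassLabel:
    """A class-index entry: species and sex behind a short code."""

    code: str
    species: str = ""
    sex: str = "n/a"          # {"female", "male", "n/a"}
    is_mosquito: bool = True

    def __post_init__(self):
        if self.sex not in ("female", "male", "n/a"):
            raise ValueError(f"invalid sex {self.sex!r} for class {self.code!r}")
        if self.sex == "n/a" and self.is_mosquito:
            raise ValueError(
                f"class {self.code!r}: sex may be n/a only for non-mosquitoes")


@dataclass
class ImageRecord:
    image_id: str
    path: str
    class_code: str
    source: str = "stereo"
    split: str = "train"
    bbox: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class DatasetManifest:
    records: list[ImageRecord]
    vocabulary: list[ClassLabel]
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        codes = [c.code for c in self.vocabulary]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate class codes in vocabulary: {dup}")
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image ids: {dup}")
        known = set(codes)
        bad = sorted({r.class_code for r in self.records if r.class_code not in known})
        if bad:
            raise ValueError(f"class codes missing from vocabulary: {bad}")

    # convenience views -----------------------------------------------------
    def subset(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def class_codes(self) -> list[str]:
        return [c.code for c in self.vocabulary]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.class_code] = out.get(r.class_code, 0) + 1
        return out


# --------------------------------------------------------------------- images

def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def crop_to_bbox(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Crop to a half-open (x0, y0, x1, y1) box; pixels are copied unchanged."""
    x0, y0, x1, y1 = bbox
    h, w = image.shape[:2]
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"bbox {bbox} invalid or outside {w}x{h} image")
    return image[y0:y1, x0:x1].copy()


def resize_image(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (H, W); returns uint8, identity when dims match."""
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"non-positive target size {target}")
    if image.shape[:2] == (th, tw):
        return image.copy()
    out = _sk_resize(image.astype(np.float64), (th, tw), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add N(0, sigma²) per pixel in [0, 255] intensity units, then clip."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, image.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def load_record_image(record: "ImageRecord",
                      resolution: tuple[int, int] | None = None) -> np.ndarray:
    """Load a record's image, crop to its bbox if any, resize if asked."""
    img = load_image(record.path)
    if record.bbox is not None:
        img = crop_to_bbox(img, record.bbox)
    if resolution is not None:
        img = resize_image(img, resolution)
    return img


# ---------------------------------------------------------------------- split

def _split_rank(seed: int, image_id: str) -> str:
    return hashlib.sha256(f"{seed}:{image_id}".encode()).hexdigest()


def split_dataset(manifest: DatasetManifest, fraction: float,
                  seed: int) -> DatasetManifest:
    """Stratified train/test split.

    Per class, the test count is ``max(1, round_half_up(n * (1 - fraction)))``
    so every class contributes test queries. Which records land in the test
    set is a pure function of ``(seed, image_id)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    by_class: dict[str, list[ImageRecord]] = {}
    for r in manifest.records:
        by_class.setdefault(r.class_code, []).append(r)
    new_records: dict[str, ImageRecord] = {}
    for code, recs in by_class.items():
        if len(recs) < 2:
            raise ValueError(f"class {code!r} has {len(recs)} image(s); "
                             "at least 2 required for a stratified split")
        n_test = max(1, math.floor(len(recs) * (1 - fraction) + 0.5))
        ranked = sorted(recs, key=lambda r: _split_rank(seed, r.image_id))
        for i, r in enumerate(ranked):
            new_records[r.image_id] = replace(
                r, split="test" if i < n_test else "train")
    records = [new_records[r.image_id] for r in manifest.records]
    return DatasetManifest(records=records, vocabulary=list(manifest.vocabulary),
                           seed=seed)


def infer_label(code: str) -> ClassLabel:
    """Build a ClassLabel from a bare code using the _f/_m suffix convention."""
    if code.endswith("_f"):
        return ClassLabel(code=code, sex="female")
    if code.endswith("_m"):
        return ClassLabel(code=code, sex="male")
    return ClassLabel(code=code, sex="n/a", is_mosquito=False)


# ------------------------------------------------------------------- manifest

_REQUIRED_COLS = ["image_id", "path", "class_code", "source", "split"]
_BBOX_COLS = ["x0", "y0", "x1", "y1"]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    has_bbox = any(r.bbox is not None for r in manifest.records)
    for r in manifest.records:
        row = {"image_id": r.image_id, "path": r.path,
               "class_code": r.class_code, "source": r.source, "split": r.split}
        if has_bbox:
            bb = r.bbox if r.bbox is not None else ("", "", "", "")
            row.update(dict(zip(_BBOX_COLS, bb)))
        rows.append(row)
    cols = _REQUIRED_COLS + (_BBOX_COLS if has_bbox else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = {
        "seed": manifest.seed,
        "vocabulary": [
            {"code": c.code, "species": c.species, "sex": c.sex,
             "is_mosquito": c.is_mosquito} for c in manifest.vocabulary],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "class_code": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        vocab = [ClassLabel(**v) for v in meta["vocabulary"]]
        seed = int(meta["seed"])
    else:
        # fall back to a vocabulary inferred from the codes present
        vocab = [infer_label(c) for c in sorted(df["class_code"].unique())]
        seed = 0
    records = []
    has_bbox = all(c in df.columns for c in _BBOX_COLS)
    for row in df.itertuples(index=False):
        bbox = None
        if has_bbox and not any(pd.isna(getattr(row, c)) or getattr(row, c) == ""
                                for c in _BBOX_COLS):
            bbox = tuple(int(getattr(row, c)) for c in _BBOX_COLS)
        records.append(ImageRecord(image_id=row.image_id, path=row.path,
                                   class_code=row.class_code, source=row.source,
                                   split=row.split, bbox=bbox))
    return DatasetManifest(records=records, vocabulary=vocab, seed=seed)
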