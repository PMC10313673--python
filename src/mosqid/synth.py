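"""Deterministic synthetic specimen imagery.

The real two-source mosquito photograph collection is available only on
request, so this module renders a parametric stand-in: each class is an
"insect" defined by a body ellipse, a pair of wings, an abdominal stripe
pattern and a body hue; each capture source applies its own background
colour, illumination gain, blur, zoom and sensor noise, emulating the
stereomicroscope-versus-mobile-phone contrast and the uncontrolled second
("external") source used for gallery extension. Classes are separable by
construction, which is exactly what the end-to-end recovery tests rely on.

Every pixel is a pure function of ``(spec, seed)``: per-image generators are
derived from ``numpy.random.SeedSequence([seed, class_index, image_index])``,
so re-running a spec reproduces the corpus bit-for-bit.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataio import (ClassLabel, DatasetManifest, ImageRecord, save_image,
                     split_dataset)

__all__ = [
    "SourceProfile", "ClassGenerator", "SyntheticSpec",
    "default_sources", "external_source", "default_class_generators",
    "demo_spec", "render_specimen", "generate_synthetic_dataset",
    "stereo_test_counts",
]

# Per-class test-set sizes of the stereomicroscope corpus (the quantity the
# worked-example confusion matrices are built on).
STEREO_TEST_COUNTS = (12, 15, 14, 26, 31, 10, 28, 12, 15, 34, 23, 15, 44, 17)
STEREO_CLASS_CODES = (
    "sAdir_f", "sAdir_m", "sAeg_f", "sAeg_m", "sAlb_f", "sAlb_m", "sAsub_f",
    "sCqui_f", "sCqui_m", "sCgel_f", "sCvis_f", "sMann_f", "sMind_f", "sMuni_f",
)


def stereo_test_counts() -> dict[str, int]:
    """Per-class stereomicroscope test counts (total 296 queries)."""
    return dict(zip(STEREO_CLASS_CODES, STEREO_TEST_COUNTS))


@dataclass(frozen=True)
class SourceProfile:
    """Rendering conditions of one capture source."""

    name: str                                # "stereo" | "phone" | "external"
    background: tuple[int, int, int]
    illumination: float = 1.0                # multiplicative gain
    blur_radius: float = 0.0                 # Gaussian blur sigma, pixels
    zoom: float = 1.0                        # specimen scale multiplier
    noise_sigma: float = 0.0                 # sensor noise, intensity units


@dataclass(frozen=True)
class ClassGenerator:
    """Parametric shape/texture family shared by all images of one class."""

    body_axes: tuple[float, float]           # semi-axes, fraction of min dim
    wing_angle: float                        # degrees from body axis
    stripe_freq: float                       # stripes along the abdomen
    hue: tuple[float, float, float]          # body RGB in [0, 1]


@dataclass
class SyntheticSpec:
    n_classes: int
    per_class_counts: list[int]
    image_size: tuple[int, int]
    sources: list[SourceProfile]
    class_generators: list[ClassGenerator]
    seed: int = 0
    train_fraction: float = 0.9
    class_codes: list[str] | None = None

    def __post_init__(self):
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if len(self.per_class_counts) != self.n_classes:
            raise ValueError("per_class_counts length must equal n_classes")
        if any(c <= 0 for c in self.per_class_counts):
            raise ValueError("per-class counts must be positive")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive")
        if len(self.class_generators) != self.n_classes:
            raise ValueError("one class generator required per class")
        if not self.sources:
            raise ValueError("at least one source profile required")
        for g in self.class_generators:
            vals = [*g.body_axes, g.wing_angle, g.stripe_freq, *g.hue]
            if not np.all(np.isfinite(vals)):
                raise ValueError("class generator parameters must be finite")
        if self.class_codes is None:
            self.class_codes = [f"syn{i:02d}_f" for i in range(self.n_classes)]


def default_sources() -> list[SourceProfile]:
    """Stereomicroscope-like and phone-like profiles (grey vs. near-white
    background, differing illumination, blur, zoom and noise)."""
    return [
        SourceProfile("stereo", background=(150, 150, 158), illumination=1.0,
                      blur_radius=0.4, zoom=1.0, noise_sigma=2.0),
        SourceProfile("phone", background=(238, 238, 234), illumination=1.08,
                      blur_radius=0.9, zoom=0.85, noise_sigma=5.0),
    ]


def external_source() -> SourceProfile:
    """Second, uncontrolled source: grey board, 2x zoom, heavier noise."""
    return SourceProfile("external", background=(120, 122, 120),
                         illumination=0.92, blur_radius=1.2, zoom=1.6,
                         noise_sigma=7.0)


def default_class_generators(n: int, seed: int = 0) -> list[ClassGenerator]:
    """`n` visually distinct parameter families, spread over hue and shape."""
    del seed  # parameters are a fixed grid; the seed only names the family
    gens = []
    for i in range(n):
        hue = (i / n + 0.07) % 1.0
        rgb = colorsys.hsv_to_rgb(hue, 0.65, 0.55)
        gens.append(ClassGenerator(
            body_axes=(0.28 + 0.10 * ((i * 3) % 5) / 4,
                       0.10 + 0.05 * ((i * 2) % 4) / 3),
            wing_angle=25.0 + 12.0 * (i % 4),
            stripe_freq=2.0 + (i % 5),
            hue=tuple(float(c) for c in rgb),
        ))
    return gens


def demo_spec(n_classes: int = 5, per_class: int = 40,
              image_size: tuple[int, int] = (64, 64), seed: int = 0,
              sources: list[SourceProfile] | None = None) -> SyntheticSpec:
    """Desk-scale corpus: `n_classes` balanced classes over two sources."""
    return SyntheticSpec(
        n_classes=n_classes,
        per_class_counts=[per_class] * n_classes,
        image_size=image_size,
        sources=sources if sources is not None else default_sources(),
        class_generators=default_class_generators(n_classes, seed),
        seed=seed,
    )


# ------------------------------------------------------------------ rendering

_SUPERSAMPLE = 3


def render_specimen(gen: ClassGenerator, source: SourceProfile,
                    image_size: tuple[int, int],
                    rng: np.random.Generator) -> np.ndarray:
    """Render one specimen image under a source profile; returns uint8 RGB."""
    h, w = image_size
    ss = _SUPERSAMPLE
    hh, ww = h * ss, w * ss
    yy, xx = np.mgrid[0:hh, 0:ww]
    # normalised coordinates in [-1, 1] on the short side
    scale = min(hh, ww) / 2.0
    x = (xx - ww / 2.0) / scale
    y = (yy - hh / 2.0) / scale

    # per-image pose jitter
    theta = np.deg2rad(rng.uniform(-20, 20))
    cx, cy = rng.uniform(-0.08, 0.08, 2)
    s = source.zoom * rng.uniform(0.92, 1.08)
    ct, st = np.cos(theta), np.sin(theta)
    u = ((x - cx) * ct + (y - cy) * st) / s
    v = (-(x - cx) * st + (y - cy) * ct) / s

    img = np.empty((hh, ww, 3))
    img[:] = np.asarray(source.background, dtype=np.float64) / 255.0

    a, b = gen.body_axes
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    stripes = 0.5 + 0.5 * np.cos(2 * np.pi * gen.stripe_freq * u / max(a, 1e-6))
    body_col = np.asarray(gen.hue)
    shade = (0.55 + 0.45 * stripes)[..., None]
    img[body] = (body_col * shade)[body]

    # wings: two translucent ellipses fanned off the thorax
    ang = np.deg2rad(gen.wing_angle)
    for sign in (1.0, -1.0):
        ca, sa = np.cos(sign * ang), np.sin(sign * ang)
        wu = (u + a * 0.25) * ca + v * sa
        wv = -(u + a * 0.25) * sa + v * ca
        wing = ((wu + a * 0.8) / (a * 0.8)) ** 2 + (wv / (b * 0.6)) ** 2 <= 1.0
        img[wing] = 0.6 * img[wing] + 0.4 * np.array([0.85, 0.85, 0.9])

    # head
    head = ((u - a * 1.05) / (b * 0.8)) ** 2 + (v / (b * 0.8)) ** 2 <= 1.0
    img[head] = body_col * 0.6

    img *= source.illumination
    # box-average down to target resolution (antialias), then degrade
    img = img.reshape(h, ss, w, ss, 3).mean(axis=(1, 3))
    if source.blur_radius > 0:
        img = gaussian_filter(img, sigma=(source.blur_radius,
                                          source.blur_radius, 0))
    img = img * 255.0
    if source.noise_sigma > 0:
        img = img + rng.normal(0.0, source.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_synthetic_dataset(spec: SyntheticSpec,
                               out_dir: str | Path) -> DatasetManifest:
    """Render the corpus to `out_dir` and return its split manifest.

    Sources are assigned round-robin within each class, so every class is
    seen under every configured capture condition. The manifest carries a
    stratified train/test split at ``spec.train_fraction``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .dataio import infer_label
    vocab = [infer_label(c) for c in spec.class_codes]
    records: list[ImageRecord] = []
    for ci, (code, count, gen) in enumerate(
            zip(spec.class_codes, spec.per_class_counts, spec.class_generators)):
        for ii in range(count):
            source = spec.sources[ii % len(spec.sources)]
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, ci, ii]))
            img = render_specimen(gen, source, spec.image_size, rng)
            image_id = f"{code}_{ii:04d}"
            rel = f"{code}/{image_id}.png"
            save_image(img, out_dir / rel)
            records.append(ImageRecord(image_id=image_id, path=str(out_dir / rel),
                                       class_code=code, source=source.name))
    manifest = DatasetManifest(records=records, vocabulary=vocab, seed=spec.seed)
    return split_dataset(manifest, spec.train_fraction, spec.seed)
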