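"""Fused image-embedding + parameter classifier for sample-level diagnosis.

One sample = one field-of-view micrograph plus the 8-dimensional population
parameter vector (3 morphology means, 3 distribution widths, deformability
mean and width).  The image contributes a 32-dimensional embedding; the
concatenated 40-dimensional feature vector feeds a fully connected stack
40 → 64 → 20 → classes with dropout, trained with softmax cross-entropy and
Adam under stratified 90/10 train/validation cycles that are re-shuffled
every cycle.

Backbone.  The image embedding comes from a compact, *untrained* seeded
convolutional filter bank (3 conv blocks, global average pooling, 32
channels): random zero-mean filters are a standard random-features embedding,
fully deterministic and dependency-free, and only the fused head is trained.
A pretrained-AlexNet backbone is accepted in the config for API parity but
raises, because it requires externally downloaded weights.

Three model variants mirror the ablation a device study runs:
``morphology`` (6 morphology parameters only), ``morphology+image`` (6 + 32),
and ``full`` (8 + 32 = 40, adding the mechanical deformability features).
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit

from .segmentation import ImageFrame

__all__ = [
    "FeatureMode",
    "ClassifierConfig",
    "FeatureVector",
    "SampleDataset",
    "FilterBankEmbedder",
    "FusedClassifier",
    "TrainResult",
    "preprocess",
    "augment",
    "embed_image",
    "assemble",
    "train",
    "predict",
    "confusion",
]

EMBEDDING_DIM = 32
N_PARAMS = 8
COMBINED_DIM = EMBEDDING_DIM + N_PARAMS  # 40


class FeatureMode(str, Enum):
    MORPHOLOGY = "morphology"  # 6 morphology parameters
    MORPHOLOGY_IMAGE = "morphology+image"  # + 32-d embedding
    FULL = "full"  # + mechanical (Dr mean, Dr width): 40-d

    @property
    def n_params(self) -> int:
        return N_PARAMS if self is FeatureMode.FULL else 6

    @property
    def uses_image(self) -> bool:
        return self is not FeatureMode.MORPHOLOGY

    @property
    def width(self) -> int:
        return self.n_params + (EMBEDDING_DIM if self.uses_image else 0)


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters.

    ``fc_sizes`` pins the fully connected stack (fused width, two hidden
    layers); the fused width 40 applies in ``full`` mode, other feature modes
    adapt the input width while keeping the hidden sizes.  Optimizer settings
    default to Adam at 1e-3 since the original protocol leaves them open.
    """

    backbone: str = "filter_bank"  # or "pretrained_alexnet" (refused: needs weights)
    feature_mode: FeatureMode = FeatureMode.FULL
    fc_sizes: tuple[int, int, int] = (COMBINED_DIM, 64, 20)
    n_classes: int = 6
    dropout_rate: float = 0.5
    augment_rotate: bool = False
    augment_crop: bool = False
    augment_flip: bool = False
    input_side: int = 224
    crop_mm: float = 0.1
    split_fraction: float = 0.9
    n_cycles: int = 3
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_mode = FeatureMode(self.feature_mode)
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.backbone not in ("filter_bank", "pretrained_alexnet"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class FeatureVector:
    """32-d image embedding + 8-d parameter vector, fused by concatenation."""

    image_embedding: np.ndarray
    params: np.ndarray

    def __post_init__(self) -> None:
        self.image_embedding = np.asarray(self.image_embedding, dtype=float).ravel()
        self.params = np.asarray(self.params, dtype=float).ravel()
        if len(self.image_embedding) != EMBEDDING_DIM:
            raise ValueError(f"image embedding must have length {EMBEDDING_DIM}")
        if len(self.params) != N_PARAMS:
            raise ValueError(f"parameter vector must have length {N_PARAMS}")

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.image_embedding, self.params])


def assemble(embedding: Sequence[float], params8: Sequence[float]) -> FeatureVector:
    """Fuse an image embedding with the 8-parameter vector (lengths checked)."""
    return FeatureVector(np.asarray(embedding), np.asarray(params8))


# --------------------------------------------------------------------------
# preprocessing / augmentation


def preprocess(
    image: ImageFrame | np.ndarray,
    pixel_scale: float | None = None,
    crop_mm: float = 0.1,
    side: int = 224,
    mode: str = "center",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Crop a fixed physical window and resize to the model raster.

    The crop is exactly ``crop_mm`` × ``crop_mm`` (default 0.1 mm), centered
    (or uniformly placed with ``mode="random"``), then resized to
    ``side`` × ``side`` with intensities scaled to [0, 1].  Fields smaller
    than the crop raise.
    """
    if isinstance(image, ImageFrame):
        px, scale = image.pixels, image.pixel_scale
    else:
        if pixel_scale is None:
            raise ValueError("pixel_scale required for a bare array")
        px, scale = np.asarray(image), pixel_scale
    crop_px = int(round(crop_mm * 1000.0 / scale))
    h, w = px.shape
    if h < crop_px or w < crop_px:
        raise ValueError(
            f"field {h}×{w} px is smaller than the {crop_px} px ({crop_mm} mm) crop"
        )
    if mode == "center":
        r0 = (h - crop_px) // 2
        c0 = (w - crop_px) // 2
    elif mode == "random":
        rng = rng or np.random.default_rng()
        r0 = int(rng.integers(0, h - crop_px + 1))
        c0 = int(rng.integers(0, w - crop_px + 1))
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    window = px[r0 : r0 + crop_px, c0 : c0 + crop_px].astype(np.float32) / 255.0
    if crop_px == side:
        return window
    return _sk_resize(window, (side, side), order=1, anti_aliasing=crop_px > side).astype(
        np.float32
    )


def augment(
    image: np.ndarray,
    seed: int | np.random.Generator,
    rotate: bool = True,
    crop: bool = True,
    flip: bool = True,
) -> np.ndarray:
    """Random rotation (0–360°, reflected padding), crop jitter, and flips.

    Deterministic given the seed; with all switches off this is the identity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float32)
    side = out.shape[0]
    if rotate:
        angle = float(rng.uniform(0.0, 360.0))
        out = _sk_rotate(out, angle, mode="reflect", preserve_range=True).astype(np.float32)
    if crop:
        frac = float(rng.uniform(0.9, 1.0))
        sz = max(int(round(side * frac)), 1)
        r0 = int(rng.integers(0, side - sz + 1))
        c0 = int(rng.integers(0, side - sz + 1))
        out = _sk_resize(
            out[r0 : r0 + sz, c0 : c0 + sz], (side, side), order=1, anti_aliasing=False
        ).astype(np.float32)
    if flip:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    return np.ascontiguousarray(out)


# --------------------------------------------------------------------------
# image backbone


class FilterBankEmbedder:
    """Untrained seeded convolutional filter bank → 32-d embedding.

    Three blocks: 8 filters 7×7 stride 4 → 16 filters 3×3 + 2×2 mean pool →
    32 filters 3×3 + 2×2 mean pool → global average pool.  Filters are
    zero-mean, unit-norm Gaussian draws from the given seed, so the embedding
    is a deterministic non-linear random-features map of the input texture.
    """

    def __init__(self, seed: int = 0) -> None:
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(self.seed, 0xF117E)))
        self.w1 = self._bank(rng, (8, 7, 7))
        self.w2 = self._bank(rng, (16, 8, 3, 3))
        self.w3 = self._bank(rng, (32, 16, 3, 3))

    @staticmethod
    def _bank(rng: np.random.Generator, shape: tuple) -> np.ndarray:
        w = rng.standard_normal(shape).astype(np.float32)
        axes = tuple(range(1, w.ndim))
        w -= w.mean(axis=axes, keepdims=True)
        w /= np.linalg.norm(w.reshape(w.shape[0], -1), axis=1).reshape(
            (-1,) + (1,) * (w.ndim - 1)
        )
        return w

    @staticmethod
    def _conv_multi(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        # x: (C, H, W); w: (O, C, k, k) -> (O, H, W), reflect padding
        out = np.empty((w.shape[0],) + x.shape[1:], dtype=np.float32)
        for o in range(w.shape[0]):
            acc = np.zeros(x.shape[1:], dtype=np.float32)
            for c in range(x.shape[0]):
                acc += ndi.correlate(x[c], w[o, c], mode="reflect")
            out[o] = acc
        return out

    @staticmethod
    def _pool2(x: np.ndarray) -> np.ndarray:
        o, h, w = x.shape
        h2, w2 = h // 2, w // 2
        return x[:, : h2 * 2, : w2 * 2].reshape(o, h2, 2, w2, 2).mean(axis=(2, 4))

    def embed(self, image01: np.ndarray) -> np.ndarray:
        """Map a [0,1] grayscale raster to the 32-vector."""
        x = np.asarray(image01, dtype=np.float32)
        if x.ndim != 2:
            raise ValueError("expected a single-channel model input")
        h1 = np.empty((8, (x.shape[0] + 3) // 4, (x.shape[1] + 3) // 4), dtype=np.float32)
        for o in range(8):
            h1[o] = ndi.correlate(x, self.w1[o], mode="reflect")[::4, ::4]
        h1 = np.maximum(h1, 0.0)
        h2 = np.maximum(self._pool2(self._conv_multi(h1, self.w2)), 0.0)
        h3 = np.maximum(self._pool2(self._conv_multi(h2, self.w3)), 0.0)
        return h3.mean(axis=(1, 2)).astype(np.float64)


def embed_image(model_input: np.ndarray, embedder: FilterBankEmbedder) -> np.ndarray:
    """Length-32 embedding of a preprocessed model input."""
    if embedder is None:
        raise ValueError("uninitialized backbone: construct a FilterBankEmbedder first")
    v = embedder.embed(model_input)
    assert len(v) == EMBEDDING_DIM
    return v


# --------------------------------------------------------------------------
# fused MLP head (numpy, Adam, dropout)


class _MLP:
    """Fully connected softmax classifier with inverted dropout."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator) -> None:
        self.sizes = list(sizes)
        self.weights = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(b) for b in sizes[1:]]

    def forward(
        self,
        x: np.ndarray,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list]:
        cache = []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
                if dropout_rate > 0.0 and rng is not None:
                    keep = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                    a = a * keep
                else:
                    keep = None
                cache.append((h, z, keep))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        # softmax
        logits = h - h.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, cache

    def train_step(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        dropout_rate: float,
        rng: np.random.Generator,
        opt_state: dict,
        lr: float,
    ) -> float:
        probs, cache = self.forward(x, dropout_rate, rng)
        n = len(x)
        loss = -float(np.mean(np.log(np.clip((probs * y_onehot).sum(axis=1), 1e-12, None))))
        delta = (probs - y_onehot) / n
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            h_in, z, keep = cache[i]
            grads_w[i] = h_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                _, z_prev, keep_prev = cache[i - 1]
                if keep_prev is not None:
                    delta = delta * keep_prev
                delta = delta * (z_prev > 0)
        self._adam(grads_w, grads_b, opt_state, lr)
        return loss

    def _adam(self, gw, gb, st, lr, b1=0.9, b2=0.999, eps=1e-8) -> None:
        if not st:
            st["t"] = 0
            st["mw"] = [np.zeros_like(w) for w in self.weights]
            st["vw"] = [np.zeros_like(w) for w in self.weights]
            st["mb"] = [np.zeros_like(b) for b in self.biases]
            st["vb"] = [np.zeros_like(b) for b in self.biases]
        st["t"] += 1
        t = st["t"]
        for i in range(len(self.weights)):
            for g, p, m, v in (
                (gw[i], self.weights[i], st["mw"], st["vw"]),
                (gb[i], self.biases[i], st["mb"], st["vb"]),
            ):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mhat = m[i] / (1 - b1**t)
                vhat = v[i] / (1 - b2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)


# --------------------------------------------------------------------------
# dataset / model / training


@dataclass
class SampleDataset:
    """Sample-level dataset: optional images, 8-param vectors, class labels."""

    params: np.ndarray  # (n, 8)
    labels: np.ndarray  # (n,) integer class indices
    images: np.ndarray | None = None  # (n, side, side) preprocessed [0,1]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.params.ndim != 2 or self.params.shape[1] != N_PARAMS:
            raise ValueError(f"params must be (n, {N_PARAMS})")
        if len(self.labels) != len(self.params):
            raise ValueError("labels and params length mismatch")
        if self.images is not None and len(self.images) != len(self.params):
            raise ValueError("images and params length mismatch")
        if not self.class_names:
            self.class_names = [str(c) for c in np.unique(self.labels)]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FusedClassifier:
    """Trained fused model: backbone seed, head weights, standardization."""

    config: ClassifierConfig
    mlp: _MLP
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    class_names: list[str]
    embedder: FilterBankEmbedder | None

    def _features(self, params: np.ndarray, images: np.ndarray | None) -> np.ndarray:
        mode = self.config.feature_mode
        p = np.atleast_2d(np.asarray(params, dtype=float))[:, : mode.n_params]
        if mode.uses_image:
            if images is None:
                raise ValueError(f"feature mode {mode.value!r} requires images")
            images = np.asarray(images)
            if images.ndim == 2:
                images = images[None]
            emb = np.stack([self.embedder.embed(im) for im in images])
            feats = np.hstack([emb, p])
        else:
            feats = p
        return (feats - self.feature_mean) / self.feature_sd

    def predict_proba(
        self, params: np.ndarray, images: np.ndarray | None = None
    ) -> np.ndarray:
        feats = self._features(params, images)
        probs, _ = self.mlp.forward(feats)
        return probs

    def predict(
        self, params: np.ndarray, images: np.ndarray | None = None
    ) -> np.ndarray:
        return self.predict_proba(params, images).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        """Single-archive .npz with config, weights and standardization."""
        cfg = dict(self.config.__dict__)
        cfg["feature_mode"] = self.config.feature_mode.value
        cfg["fc_sizes"] = list(self.config.fc_sizes)
        arrays = {
            "feature_mean": self.feature_mean,
            "feature_sd": self.feature_sd,
        }
        for i, (w, b) in enumerate(zip(self.mlp.weights, self.mlp.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        arrays["meta"] = np.frombuffer(
            json.dumps(
                {
                    "config": cfg,
                    "class_names": self.class_names,
                    "sizes": self.mlp.sizes,
                    "n_layers": len(self.mlp.weights),
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FusedClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            cfg = ClassifierConfig(**{**meta["config"], "fc_sizes": tuple(meta["config"]["fc_sizes"])})
            mlp = _MLP(meta["sizes"], np.random.default_rng(0))
            mlp.weights = [z[f"w{i}"] for i in range(meta["n_layers"])]
            mlp.biases = [z[f"b{i}"] for i in range(meta["n_layers"])]
            embedder = FilterBankEmbedder(cfg.seed) if FeatureMode(cfg.feature_mode).uses_image else None
            return cls(
                config=cfg,
                mlp=mlp,
                feature_mean=z["feature_mean"],
                feature_sd=z["feature_sd"],
                class_names=meta["class_names"],
                embedder=embedder,
            )


@dataclass
class TrainResult:
    model: FusedClassifier
    cycle_accuracies: list[float]
    final_confusion: np.ndarray

    def summary(self) -> str:
        accs = ", ".join(f"{a:.1%}" for a in self.cycle_accuracies)
        return (
            f"Fused classifier ({self.model.config.feature_mode.value}, "
            f"{len(self.model.class_names)} classes)\n"
            f"  validation accuracy per cycle: {accs}\n"
            f"  mean: {np.mean(self.cycle_accuracies):.1%}"
        )


def train(dataset: SampleDataset, config: ClassifierConfig) -> TrainResult:
    """Train the fused head under stratified, re-shuffled 90/10 cycles.

    Each cycle draws a fresh stratified split (development fraction
    ``split_fraction``), standardizes features on the development split,
    trains the MLP with dropout, and records validation accuracy.  The model
    returned is the one from the final cycle.  Deterministic given
    ``config.seed``.
    """
    if config.backbone == "pretrained_alexnet":
        raise RuntimeError(
            "the pretrained-AlexNet backbone requires externally downloaded "
            "weights; use the default filter_bank backbone"
        )
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    mode = config.feature_mode
    if mode.uses_image and dataset.images is None:
        raise ValueError(f"feature mode {mode.value!r} requires images in the dataset")

    ss = np.random.SeedSequence(entropy=(int(config.seed), 0xA11CE))
    embedder = FilterBankEmbedder(config.seed) if mode.uses_image else None
    if mode.uses_image:
        embeddings = np.stack([embedder.embed(im) for im in dataset.images])
        raw_feats = np.hstack([embeddings, dataset.params[:, : mode.n_params]])
    else:
        raw_feats = dataset.params[:, : mode.n_params].copy()
    if mode is FeatureMode.FULL and raw_feats.shape[1] != config.fc_sizes[0]:
        raise ValueError(
            f"fused width {raw_feats.shape[1]} does not match fc_sizes[0]="
            f"{config.fc_sizes[0]}"
        )

    n_classes = len(classes)
    accs: list[float] = []
    model: FusedClassifier | None = None
    conf = np.zeros((n_classes, n_classes), dtype=int)
    cycle_seeds = ss.spawn(config.n_cycles)
    for cycle, cseed in enumerate(cycle_seeds):
        rng = np.random.default_rng(cseed)
        split_state = int(rng.integers(0, 2**31 - 1))
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=config.split_fraction, random_state=split_state
        )
        (train_idx, val_idx), = splitter.split(raw_feats, labels)
        mean = raw_feats[train_idx].mean(axis=0)
        sd = raw_feats[train_idx].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        xtr = (raw_feats[train_idx] - mean) / sd
        xva = (raw_feats[val_idx] - mean) / sd
        ytr = labels[train_idx]
        onehot = np.eye(n_classes)[np.searchsorted(classes, ytr)]
        mlp = _MLP([raw_feats.shape[1], *config.fc_sizes[1:], n_classes], rng)
        opt_state: dict = {}
        n_tr = len(xtr)
        for epoch in range(config.epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, config.batch_size):
                idx = order[start : start + config.batch_size]
                mlp.train_step(
                    xtr[idx], onehot[idx], config.dropout_rate, rng, opt_state,
                    config.learning_rate,
                )
        probs, _ = mlp.forward(xva)
        pred = classes[probs.argmax(axis=1)]
        accs.append(float(np.mean(pred == labels[val_idx])))
        conf = _sk_confusion(labels[val_idx], pred, labels=classes)
        model = FusedClassifier(
            config=config,
            mlp=mlp,
            feature_mean=mean,
            feature_sd=sd,
            class_names=dataset.class_names,
            embedder=embedder,
        )
    return TrainResult(model=model, cycle_accuracies=accs, final_confusion=conf)


def predict(
    model: FusedClassifier, params: np.ndarray, image: np.ndarray | None = None
) -> tuple[np.ndarray, str]:
    """Class probabilities and the argmax label for one sample."""
    images = image[None] if (image is not None and image.ndim == 2) else image
    probs = model.predict_proba(np.atleast_2d(params), images)[0]
    return probs, model.class_names[int(probs.argmax())]


def confusion(
    model: FusedClassifier,
    dataset: SampleDataset,
) -> np.ndarray:
    """Confusion matrix (rows = true classes) over a dataset."""
    pred = model.predict(dataset.params, dataset.images)
    return _sk_confusion(dataset.labels, pred, labels=np.unique(dataset.labels))
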