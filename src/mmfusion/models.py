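"""The seven model variants: unimodal baselines and Early/Late/Model fusion.

Models are described declaratively by :class:`FusionModelSpec` following the
``ModelName(text kernel, image kernel, pretraining)`` naming convention, and
instantiated over one of two backbones:

* ``tiny_test`` — three 3x3 conv blocks (16/32/64 filters, 2x2 max pool),
  sized for CPU-scale experiments;
* ``densenet121`` — the standard DenseNet-121 feature extractor for
  full-scale 224x224 inputs.

Fusion strategies:

* **Early fusion** stacks the text embedding matrix under the image to form a
  single augmented input grid processed by one CNN.
* **Late fusion** trains the two unimodal models independently and averages
  their output class distributions.
* **Model fusion** concatenates the flattened terminal feature maps of an
  image branch and a text branch into a shared dense head, trained end to end.

Classification heads follow one layout everywhere: two fully connected ReLU
layers, batch normalisation, dropout 0.5, and a final linear output layer read
through softmax (single-label) or sigmoid (multi-label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .nn import (BatchNorm, Conv2D, Dense, Dropout, Flatten, GlobalMaxPool,
                 Layer, Parameter, Pool2D, ReLU, Sequential, TwoBranchNet,
                 densenet121_features, sigmoid, softmax)
from .nn.net import iter_layers

VALID_MODEL_NAMES = ("image_only", "text_only", "early_fusion", "late_fusion",
                     "model_fusion")


@dataclass(frozen=True)
class FusionModelSpec:
    """Declarative description of one model variant."""

    model_name: str
    text_kernel: str = "none"    # square | wide | none
    image_kernel: str = "none"   # square | none
    pretrained: bool = False
    backbone: str = "tiny_test"  # tiny_test | densenet121
    head: str = "softmax_cce"    # softmax_cce | sigmoid_bce
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.model_name not in VALID_MODEL_NAMES:
            raise ValueError(f"unknown model_name {self.model_name!r}")
        if self.text_kernel not in ("square", "wide", "none"):
            raise ValueError(f"unknown text_kernel {self.text_kernel!r}")
        if self.image_kernel not in ("square", "none"):
            raise ValueError(f"unknown image_kernel {self.image_kernel!r}")
        if self.head not in ("softmax_cce", "sigmoid_bce"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.backbone not in ("tiny_test", "densenet121"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        name = self.model_name
        if name == "image_only":
            if self.text_kernel != "none" or self.image_kernel != "square":
                raise ValueError("image_only requires image_kernel=square and "
                                 "text_kernel=none")
        elif name == "text_only":
            if self.text_kernel not in ("square", "wide") or self.image_kernel != "none":
                raise ValueError("text_only requires a text kernel and "
                                 "image_kernel=none")
        elif name == "early_fusion":
            # one joint branch: (square, square) or a wide joint kernel
            ok = (self.text_kernel == "square" and self.image_kernel == "square") or \
                 (self.text_kernel == "wide" and self.image_kernel == "none")
            if not ok:
                raise ValueError("early_fusion requires (square, square) or "
                                 "(wide, none) kernels — it has one joint branch")
        else:  # late_fusion / model_fusion need both modality branches
            if self.text_kernel == "none" or self.image_kernel == "none":
                raise ValueError(f"{name} requires both a text and an image kernel")
        if self.pretrained and name not in ("late_fusion", "model_fusion"):
            raise ValueError("pretrained initialisation applies only to "
                             "late_fusion and model_fusion")

    @property
    def joint_kernel(self) -> str:
        """Kernel style of the single early-fusion branch."""
        if self.model_name != "early_fusion":
            raise ValueError("joint_kernel is defined for early_fusion only")
        return self.text_kernel

    @property
    def name(self) -> str:
        """Human-readable name in the ModelName(kernels[, Pretrained]) style."""
        titles = {"image_only": "Image Only", "text_only": "Text Only",
                  "early_fusion": "Early Fusion", "late_fusion": "Late Fusion",
                  "model_fusion": "Model Fusion"}
        if self.model_name == "image_only":
            parts = [self.image_kernel.title()]
        elif self.model_name in ("text_only", "early_fusion"):
            parts = [self.text_kernel.title()]
        else:
            parts = [self.text_kernel.title(), self.image_kernel.title()]
        if self.pretrained:
            parts.append("Pretrained")
        return f"{titles[self.model_name]} ({', '.join(parts)})"


@dataclass
class ArchitectureConfig:
    """Capacity knobs shared by every variant (interface contracts do not
    depend on these; defaults are conventional)."""

    conv_channels: tuple[int, ...] = (16, 32, 64)
    wide_filters: int = 64
    wide_kernel_heights: tuple[int, ...] = (2, 3)
    fc_dims: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    n_channels: int = 1


def validate_distribution(p: np.ndarray, mode: str, tol: float = 1e-6) -> None:
    """Check the simplex (softmax) or box (sigmoid) constraint."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValueError("class scores must lie in [0, 1]")
    if mode == "softmax_cce":
        sums = p.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > tol * p.shape[-1]):
            raise ValueError("softmax-mode distribution must sum to 1")


# ---------------------------------------------------------------------------
# fusion primitives
# ---------------------------------------------------------------------------

def build_early_fusion_input(image: np.ndarray, text: np.ndarray) -> np.ndarray:
    """Stack an image block on top of a text-embedding block row-wise.

    A 224x224xC image and a 200x224 text matrix yield a 424x224xC grid: rows
    ``0..H-1`` are the image, rows ``H..H+L-1`` the text (replicated across the
    C channels).  Accepts single samples or batches (leading batch axis).
    """
    image = np.asarray(image)
    text = np.asarray(text)
    batched = image.ndim == 4
    if not batched:
        # single sample: image (H,W) or (H,W,C); text (L,d) or (L,d,C)
        if image.ndim == 2:
            image = image[..., None]
        if image.ndim != 3:
            raise ValueError("image must be (H,W), (H,W,C) or a (N,H,W,C) batch")
        image = image[None]
        if text.ndim == 2:
            text = text[..., None]
        if text.ndim != 3:
            raise ValueError("unbatched text must be (L,d) or (L,d,C)")
        text = text[None]
    else:
        # batch: text (N,L,d) or (N,L,d,C)
        if text.ndim == 3:
            text = text[..., None]
        if text.ndim != 4:
            raise ValueError("batched text must be (N,L,d) or (N,L,d,C)")
    if text.shape[-1] == 1 and image.shape[-1] > 1:
        text = np.repeat(text, image.shape[-1], axis=-1)
    if image.shape[2] != text.shape[2]:
        raise ValueError(
            f"width mismatch: image width {image.shape[2]} != text embedding "
            f"dimension {text.shape[2]}; early fusion requires equal widths")
    if image.shape[-1] != text.shape[-1]:
        raise ValueError("image and text blocks must have equal channel counts")
    out = np.concatenate([image, text], axis=1)
    return out if batched else out[0]


def late_fuse(dist_image: np.ndarray, dist_text: np.ndarray,
              mode: str = "softmax_cce") -> np.ndarray:
    """Element-wise arithmetic mean of two class distributions."""
    a = np.asarray(dist_image, dtype=np.float64)
    b = np.asarray(dist_text, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"distribution shape mismatch: {a.shape} vs {b.shape}")
    validate_distribution(a, mode)
    validate_distribution(b, mode)
    return 0.5 * (a + b)


def model_fuse_features(feat_image: np.ndarray, feat_text: np.ndarray) -> np.ndarray:
    """Concatenate flattened per-modality feature vectors (order-preserving)."""
    a = np.ravel(np.asarray(feat_image, dtype=np.float64))
    b = np.ravel(np.asarray(feat_text, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot fuse an empty feature vector")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("feature vectors must be finite")
    return np.concatenate([a, b])


def preprocess_image(raw: np.ndarray, target: int = 224, resize: int | None = 256,
                     grayscale: bool = False) -> np.ndarray:
    """Bilinear resize to ``resize`` then exact center crop to ``target``.

    ``resize=None`` disables the intermediate resize: inputs already at the
    target size pass through unchanged, anything else is resized directly.
    """
    img = np.asarray(raw, dtype=np.float64)
    if img.ndim == 3 and grayscale:
        img = img @ np.array([0.299, 0.587, 0.114])  # ITU-R 601 luma
    if img.ndim != 2:
        if img.ndim == 3:
            return np.stack([preprocess_image(img[..., c], target, resize)
                             for c in range(img.shape[-1])], axis=-1)
        raise ValueError("expected a 2-D or 3-D image")

    def _resize(a: np.ndarray, size: int) -> np.ndarray:
        pil = Image.fromarray(a.astype(np.float32), mode="F")
        return np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float64)

    if resize is None:
        if img.shape == (target, target):
            return img.copy()
        return _resize(img, target)
    img = _resize(img, resize)
    off = (resize - target) // 2
    return img[off:off + target, off:off + target].copy()


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

class MultiKernelConv(Layer):
    """Parallel wide-kernel convolutions with max-over-time pooling.

    Each kernel spans the full input width (k x d), so convolution slides along
    the token axis only; pooled outputs are concatenated into one vector.
    """

    def __init__(self, in_ch: int, width: int, heights: tuple[int, ...],
                 filters: int, rng: np.random.Generator):
        self.banks = [Sequential([
            Conv2D(in_ch, filters, kh, width, pad=0, rng=rng),
            ReLU(), GlobalMaxPool()]) for kh in heights]

    @property
    def params(self) -> list[Parameter]:
        return [p for bank in self.banks for p in bank.params]

    def children(self):
        return self.banks

    def forward(self, x, train: bool = False):
        outs = [bank.forward(x, train=train) for bank in self.banks]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        pieces = np.split(grad, self._splits, axis=1)
        gx = None
        for bank, g in zip(self.banks, pieces):
            gb = bank.backward(g)
            gx = gb if gx is None else gx + gb
        return gx


def _square_extractor(arch: ArchitectureConfig, backbone: str,
                      rng: np.random.Generator) -> Sequential:
    if backbone == "densenet121":
        return Sequential([densenet121_features(arch.n_channels, rng), Flatten()])
    layers: list[Layer] = []
    in_ch = arch.n_channels
    for ch in arch.conv_channels:
        layers += [Conv2D(in_ch, ch, 3, 3, pad="same", rng=rng),
                   BatchNorm(ch), ReLU(), Pool2D(2, kind="max")]
        in_ch = ch
    layers.append(Flatten())
    return Sequential(layers)


def _wide_extractor(arch: ArchitectureConfig, width: int,
                    rng: np.random.Generator) -> Sequential:
    return Sequential([MultiKernelConv(arch.n_channels, width,
                                       arch.wide_kernel_heights,
                                       arch.wide_filters, rng)])


def _feature_dim(extractor: Sequential, input_shape: tuple[int, ...]) -> int:
    probe = np.zeros((1,) + input_shape)
    return extractor.forward(probe, train=False).shape[1]


def _head(in_dim: int, n_classes: int, arch: ArchitectureConfig,
          rng: np.random.Generator) -> Sequential:
    f1, f2 = arch.fc_dims
    return Sequential([
        Dense(in_dim, f1, rng=rng), ReLU(),
        Dense(f1, f2, rng=rng), ReLU(),
        BatchNorm(f2),
        Dropout(arch.dropout, rng=np.random.default_rng(rng.integers(2**31))),
        Dense(f2, n_classes, rng=rng),
    ])


class FusionModel:
    """A trainable model plus its input-assembly rule.

    ``features``/``head`` references support pretrained-weight transfer;
    ``predict_proba`` applies the head activation (softmax or sigmoid) to the
    network logits in evaluation mode.
    """

    def __init__(self, spec: FusionModelSpec, net: Layer,
                 features: Sequential | None, head: Sequential | None,
                 make_input):
        self.spec = spec
        self.net = net
        self.features = features
        self.head = head
        self.make_input = make_input

    def forward_logits(self, x, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def predict_proba(self, x_image: np.ndarray | None,
                      x_text: np.ndarray | None) -> np.ndarray:
        logits = self.forward_logits(self.make_input(x_image, x_text), train=False)
        act = softmax if self.spec.head == "softmax_cce" else sigmoid
        return act(logits)


class LateFusionModel:
    """Two independently trained unimodal models fused by output averaging."""

    def __init__(self, spec: FusionModelSpec, image_model: FusionModel,
                 text_model: FusionModel):
        self.spec = spec
        self.image_model = image_model
        self.text_model = text_model

    @property
    def submodels(self) -> list[FusionModel]:
        return [self.image_model, self.text_model]

    def predict_proba(self, x_image: np.ndarray, x_text: np.ndarray) -> np.ndarray:
        return late_fuse(self.image_model.predict_proba(x_image, None),
                         self.text_model.predict_proba(None, x_text),
                         mode=self.spec.head)


def _ensure_4d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return x[..., None] if x.ndim == 3 else x


def build_model(spec: FusionModelSpec, image_size: int = 224,
                text_len: int = 200, embed_dim: int = 224,
                arch: ArchitectureConfig | None = None,
                seed: int = 0) -> FusionModel | LateFusionModel:
    """Instantiate a trainable model for a spec.

    ``image_size``/``text_len``/``embed_dim`` fix the input geometry (224 /
    200 / 224 at full scale).  All weight initialisation derives from
    ``seed``.
    """
    arch = arch or ArchitectureConfig()
    model = _build_model(spec, image_size, text_len, embed_dim, arch, seed)
    model.geometry = {"image_size": image_size, "text_len": text_len,
                      "embed_dim": embed_dim, "seed": seed}
    model.arch = arch
    return model


def _build_model(spec, image_size, text_len, embed_dim, arch, seed):
    rng = np.random.default_rng(seed)
    n_ch = arch.n_channels
    name = spec.model_name

    if name == "late_fusion":
        img_spec = FusionModelSpec("image_only", "none", spec.image_kernel,
                                   backbone=spec.backbone, head=spec.head,
                                   n_classes=spec.n_classes)
        txt_spec = FusionModelSpec("text_only", spec.text_kernel, "none",
                                   backbone=spec.backbone, head=spec.head,
                                   n_classes=spec.n_classes)
        return LateFusionModel(
            spec,
            build_model(img_spec, image_size, text_len, embed_dim, arch,
                        seed=int(rng.integers(2**31))),
            build_model(txt_spec, image_size, text_len, embed_dim, arch,
                        seed=int(rng.integers(2**31))))

    if name == "image_only":
        features = _square_extractor(arch, spec.backbone, rng)
        fdim = _feature_dim(features, (image_size, image_size, n_ch))
        head = _head(fdim, spec.n_classes, arch, rng)
        net = Sequential([features, head])
        return FusionModel(spec, net, features, head,
                           lambda xi, xt: _ensure_4d(xi))

    if name == "text_only":
        if spec.text_kernel == "wide":
            features = _wide_extractor(arch, embed_dim, rng)
        else:
            features = _square_extractor(arch, spec.backbone, rng)
        fdim = _feature_dim(features, (text_len, embed_dim, n_ch))
        head = _head(fdim, spec.n_classes, arch, rng)
        net = Sequential([features, head])
        return FusionModel(spec, net, features, head,
                           lambda xi, xt: _ensure_4d(xt))

    if name == "early_fusion":
        rows = image_size + text_len
        if spec.joint_kernel == "wide":
            features = _wide_extractor(arch, embed_dim, rng)
        else:
            features = _square_extractor(arch, spec.backbone, rng)
        fdim = _feature_dim(features, (rows, embed_dim, n_ch))
        head = _head(fdim, spec.n_classes, arch, rng)
        net = Sequential([features, head])
        return FusionModel(
            spec, net, features, head,
            lambda xi, xt: build_early_fusion_input(_ensure_4d(xi), xt))

    # model_fusion: two branches into a joint head, end to end
    img_feat = _square_extractor(arch, spec.backbone, rng)
    txt_feat = _wide_extractor(arch, embed_dim, rng) if spec.text_kernel == "wide" \
        else _square_extractor(arch, spec.backbone, rng)
    fdim = (_feature_dim(img_feat, (image_size, image_size, n_ch))
            + _feature_dim(txt_feat, (text_len, embed_dim, n_ch)))
    head = _head(fdim, spec.n_classes, arch, rng)
    net = TwoBranchNet(img_feat, txt_feat, head)
    model = FusionModel(spec, net, None, head,
                        lambda xi, xt: (_ensure_4d(xi), _ensure_4d(xt)))
    model.image_features = img_feat
    model.text_features = txt_feat
    return model


def transfer_pretrained_weights(image_model: FusionModel, text_model: FusionModel,
                                fusion_model: "FusionModel | LateFusionModel"):
    """Initialise a fusion model's branches from trained unimodal models.

    Copies every feature-extractor parameter of the matching branch; head
    parameters keep their fresh initialisation and nothing is frozen, so
    fine-tuning continues end to end.  Early fusion has no separable branches
    and is rejected.
    """
    spec = fusion_model.spec
    if spec.model_name == "early_fusion":
        raise ValueError("early_fusion has a single joint branch; unimodal "
                         "weights cannot be transferred into it")
    if spec.model_name == "late_fusion":
        pairs = [(image_model.features, fusion_model.image_model.features),
                 (text_model.features, fusion_model.text_model.features)]
    elif spec.model_name == "model_fusion":
        pairs = [(image_model.features, fusion_model.image_features),
                 (text_model.features, fusion_model.text_features)]
    else:
        raise ValueError("transfer target must be a fusion model")
    for src, dst in pairs:
        sp, dp = src.params, dst.params
        if len(sp) != len(dp):
            raise ValueError(f"branch topology mismatch: {len(sp)} vs {len(dp)} "
                             "parameter tensors")
        for i, (a, b) in enumerate(zip(sp, dp)):
            if a.value.shape != b.value.shape:
                raise ValueError(f"branch topology mismatch at parameter {i} "
                                 f"({a.name}): {a.value.shape} vs {b.value.shape}")
        for a, b in zip(sp, dp):
            b.value[...] = a.value
        # running batch-norm statistics travel with the weights
        src_bns = [l for l in iter_layers(src) if isinstance(l, BatchNorm)]
        dst_bns = [l for l in iter_layers(dst) if isinstance(l, BatchNorm)]
        for sbn, dbn in zip(src_bns, dst_bns):
            dbn.running_mean[...] = sbn.running_mean
            dbn.running_var[...] = sbn.running_var
    return fusion_model


def save_model(model: "FusionModel | LateFusionModel", path: str) -> None:
    """Persist a trained model: ``<path>.npz`` weights plus a ``<path>.json``
    sidecar recording the spec, input geometry and seed."""
    import json
    from dataclasses import asdict
    from pathlib import Path as _P

    from .nn import get_weights

    base = _P(path)
    if isinstance(model, LateFusionModel):
        arrays = {}
        for tag, sub in (("image", model.image_model), ("text", model.text_model)):
            for i, w in enumerate(get_weights(sub.net)):
                arrays[f"{tag}_{i}"] = w
    else:
        arrays = {f"w_{i}": w for i, w in enumerate(get_weights(model.net))}
    np.savez(base.with_suffix(".npz"), **arrays)
    sidecar = {"spec": asdict(model.spec), "geometry": model.geometry,
               "arch": asdict(getattr(model, "arch", None) or ArchitectureConfig())}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str) -> "FusionModel | LateFusionModel":
    """Rebuild a model from :func:`save_model` output."""
    import json
    from pathlib import Path as _P

    from .nn import set_weights

    base = _P(path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    spec = FusionModelSpec(**sidecar["spec"])
    geo = sidecar["geometry"]
    arch_d = sidecar["arch"]
    for key in ("conv_channels", "wide_kernel_heights", "fc_dims"):
        arch_d[key] = tuple(arch_d[key])
    model = build_model(spec, image_size=geo["image_size"],
                        text_len=geo["text_len"], embed_dim=geo["embed_dim"],
                        arch=ArchitectureConfig(**arch_d), seed=geo["seed"])
    with np.load(base.with_suffix(".npz")) as data:
        if isinstance(model, LateFusionModel):
            for tag, sub in (("image", model.image_model),
                             ("text", model.text_model)):
                keys = sorted((k for k in data.files if k.startswith(tag + "_")),
                              key=lambda k: int(k.rsplit("_", 1)[1]))
                set_weights(sub.net, [data[k] for k in keys])
        else:
            keys = sorted(data.files, key=lambda k: int(k.rsplit("_", 1)[1]))
            set_weights(model.net, [data[k] for k in keys])
    return model


def standard_specs(head: str, n_classes: int,
                   backbone: str = "tiny_test") -> list[FusionModelSpec]:
    """The study's eight model variants (two unimodal, six fusion)."""
    mk = lambda *a, **k: FusionModelSpec(*a, backbone=backbone, head=head,
                                         n_classes=n_classes, **k)
    return [
        mk("image_only", "none", "square"),
        mk("text_only", "wide", "none"),
        mk("early_fusion", "square", "square"),
        mk("early_fusion", "wide", "none"),
        mk("late_fusion", "wide", "square"),
        mk("late_fusion", "wide", "square", pretrained=True),
        mk("model_fusion", "wide", "square"),
        mk("model_fusion", "wide", "square", pretrained=True),
    ]
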