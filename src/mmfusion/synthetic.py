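"""Synthetic paired image/text datasets with controllable modality signal.

The generator emulates the statistical skeleton of a radiology dataset: each
patient contributes 1-2 grayscale images and one free-text report, labelled
either with a single 2-class outcome (normal/abnormal, softmax head) or an
11-way multi-label finding vector (sigmoid head), with configurable label
imbalance.

Signal model
------------
For every labelled outcome the generator draws a latent *evidence* value per
modality::

    v_img = d_i * (y - 1/2) + sqrt(ov) * s + sqrt(1 - ov) * e_img
    v_txt = d_t * (y - 1/2) + sqrt(ov) * s + sqrt(1 - ov) * e_txt

with ``s, e_img, e_txt ~ N(0, 1)`` and separations ``d_i = 3 * image_signal``,
``d_t = 3 * text_signal``.  ``signal_overlap`` (``ov``) interpolates between
fully shared noise (both modalities carry the same class evidence, fusing them
adds nothing) and independent noise (evidence is complementary and the Bayes
AUC of the fused statistic exceeds either single modality).  Because the
evidence variables are Gaussian, single- and fused-modality Bayes AUCs have
closed forms, which the tests exploit.

The image renders each evidence value as the contrast of a class-specific bar
motif on a noisy background; the report encodes it as the rate of
class-specific finding keywords among filler tokens.  Setting a signal to 0
makes that modality statistically independent of the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

EVIDENCE_SCALE = 3.0  # separation d at signal=1; Bayes AUC = Phi(d / sqrt(2))
KEYWORDS_PER_CLASS = 8  # class evidence spread over several rarer terms
KEYWORD_RATE = 0.25    # expected fraction of report tokens that are findings terms
_BAR_FRACTION = 0.55  # motif contrast ceiling
_BACKGROUND = 0.15
_PIXEL_NOISE = 0.04


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study population."""

    n_patients: int
    images_per_patient: tuple[int, int] = (1, 2)
    task_mode: str = "binary_softmax"  # or "multilabel_sigmoid"
    n_classes: int = 2
    image_size: int = 224
    image_signal: float = 0.5
    text_signal: float = 0.5
    signal_overlap: float = 0.5
    imbalance: float = 1.77
    vocab_size: int = 300
    report_length: tuple[int, int] = (15, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("cannot generate an empty dataset: n_patients must be >= 1")
        for name in ("image_signal", "text_signal", "signal_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.imbalance < 1.0:
            raise ValueError("imbalance is a majority:minority ratio and must be >= 1")
        if self.task_mode not in ("binary_softmax", "multilabel_sigmoid"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        if self.task_mode == "binary_softmax" and self.n_classes != 2:
            raise ValueError("binary_softmax requires n_classes == 2")
        n_kw = KEYWORDS_PER_CLASS * self._n_evidence_cats()
        if self.vocab_size <= n_kw:
            raise ValueError(f"vocab_size must exceed {n_kw} keyword tokens")

    def _n_evidence_cats(self) -> int:
        # binary mode: one evidence dimension, but two keyword sets
        # (abnormal- and normal-indicating); multilabel: one per class
        return 2 if self.task_mode == "binary_softmax" else self.n_classes

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("images_per_patient", "report_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class MultimodalSample:
    """One patient record: image(s), tokenised report, binary label vector."""

    patient_id: str
    images: list[np.ndarray]
    report: list[str]
    labels: np.ndarray
    latent: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a sample must carry at least one image")
        self.labels = np.asarray(self.labels, dtype=np.int64)


def _keywords(cat: int) -> list[str]:
    return [f"finding{cat}x{j}" for j in range(KEYWORDS_PER_CLASS)]


def _render_image(v_img: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render evidence bars plus the nuisance structure of real radiographs.

    Evidence: bar ``c`` sits inside grid cell ``c`` with contrast
    ``sigmoid(v_c)``; position jitters within the cell.  Nuisance: a smooth
    low-frequency background, white pixel noise, distractor bars at random
    positions, and a global brightness/contrast jitter per image.  The
    nuisance makes pixel-level decoding sample-limited (a classifier must
    localise the evidence cell against distractors under varying gain), which
    is what makes image-side learning data-hungry, as with real
    radiographs — while the latent evidence ``v_c`` keeps its closed form.
    """
    # smooth background + white noise
    blocks = max(1, size // 8)
    coarse = rng.normal(0.0, 0.10, size=(blocks, blocks))
    bg = np.kron(coarse, np.ones((size // blocks + 1, size // blocks + 1)))
    img = _BACKGROUND + bg[:size, :size] + rng.normal(0.0, _PIXEL_NOISE,
                                                      size=(size, size))
    # distractor bars: class-independent structure whose contrast range
    # overlaps the evidence bars', so decoding requires localisation
    for _ in range(5):
        h = max(1, size // 10)
        w = max(2, size // 3)
        y = int(rng.integers(0, size - h))
        x = int(rng.integers(0, max(1, size - w)))
        img[y:y + h, x:x + w] += rng.uniform(0.05, 0.45)

    n = len(v_img)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    ch, cw = size // nrows, size // ncols
    amp = _BAR_FRACTION / (1.0 + np.exp(-v_img))
    for c in range(n):
        r, q = divmod(c, ncols)
        top, left = r * ch, q * cw
        bar_h = max(1, ch // 4)
        bar_w = max(2, (2 * cw) // 3)
        y0 = top + int(rng.integers(0, max(1, ch - bar_h)))
        x0 = left + int(rng.integers(0, max(1, cw - bar_w)))
        img[y0:y0 + bar_h, x0:x0 + bar_w] += amp[c]
    # global gain/offset jitter
    gain = rng.uniform(0.8, 1.2)
    offset = rng.uniform(-0.06, 0.06)
    img = gain * (img - _BACKGROUND) + _BACKGROUND + offset
    return np.clip(img, 0.0, 1.0)


def _sample_report(weights: np.ndarray, keyword_sets: list[list[str]],
                   fillers: list[str], filler_p: np.ndarray, length: int,
                   rng: np.random.Generator) -> list[str]:
    """Each token: pick a keyword category with prob weights[c], else a filler."""
    report = []
    cat_p = np.concatenate([weights, [1.0 - weights.sum()]])
    cats = rng.choice(len(cat_p), size=length, p=cat_p)
    for cat in cats:
        if cat < len(keyword_sets):
            report.append(keyword_sets[cat][rng.integers(len(keyword_sets[cat]))])
        else:
            report.append(fillers[rng.choice(len(fillers), p=filler_p)])
    return report


def generate_dataset(config: GeneratorConfig) -> list[MultimodalSample]:
    """Draw a complete dataset; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    binary = config.task_mode == "binary_softmax"
    n_evid = 1 if binary else config.n_classes
    d_img = EVIDENCE_SCALE * config.image_signal
    d_txt = EVIDENCE_SCALE * config.text_signal
    ov = config.signal_overlap

    n_cats = config._n_evidence_cats()
    keyword_sets = [_keywords(c) for c in range(n_cats)]
    n_fill = config.vocab_size - KEYWORDS_PER_CLASS * n_cats
    fillers = [f"note{i}" for i in range(n_fill)]
    filler_p = 1.0 / np.arange(1, n_fill + 1)  # Zipf-like filler frequencies
    filler_p /= filler_p.sum()

    p_major = config.imbalance / (1.0 + config.imbalance)
    samples: list[MultimodalSample] = []
    for i in range(config.n_patients):
        pid = f"patient{i:05d}"
        if binary:
            y_abn = int(rng.random() < p_major)  # abnormal is the majority class
            labels = np.zeros(2, dtype=np.int64)
            labels[y_abn] = 1
            y_evid = np.array([float(y_abn)])
        else:
            # positives are the minority at rate 1 / (1 + imbalance) per class
            y_vec = (rng.random(config.n_classes) < 1.0 / (1.0 + config.imbalance))
            labels = y_vec.astype(np.int64)
            y_evid = labels.astype(float)

        s = rng.normal(size=n_evid)
        e_img = rng.normal(size=n_evid)
        e_txt = rng.normal(size=n_evid)
        centered = y_evid - 0.5
        v_img = d_img * centered + np.sqrt(ov) * s + np.sqrt(1.0 - ov) * e_img
        v_txt = d_txt * centered + np.sqrt(ov) * s + np.sqrt(1.0 - ov) * e_txt

        n_img = int(rng.integers(config.images_per_patient[0],
                                 config.images_per_patient[1] + 1))
        images = [_render_image(v_img, config.image_size, rng) for _ in range(n_img)]

        sig_txt = 1.0 / (1.0 + np.exp(-v_txt))
        if binary:
            # abnormal- and normal-indicating findings terms; their joint rate
            # stays at KEYWORD_RATE so most tokens are filler, as in reports
            weights = np.array([KEYWORD_RATE * (1.0 - sig_txt[0]),
                                KEYWORD_RATE * sig_txt[0]])
        else:
            weights = (2.0 * KEYWORD_RATE / n_evid) * sig_txt
        length = int(rng.integers(config.report_length[0],
                                  config.report_length[1] + 1))
        report = _sample_report(weights, keyword_sets, fillers, filler_p,
                                length, rng)

        samples.append(MultimodalSample(
            patient_id=pid, images=images, report=report, labels=labels,
            latent={"v_image": v_img, "v_text": v_txt, "y": y_evid}))
    return samples


def write_dataset(samples: list[MultimodalSample], out_dir: str | Path,
                  overwrite: bool = False) -> Path:
    """Write PNG images plus a ``metadata.csv`` table (one row per patient).

    Columns: patient_id, pipe-delimited relative image paths, the report as a
    space-joined token string, and the label vector pipe-delimited as 0/1
    flags.  Images are quantised to 8-bit grayscale PNG.
    """
    if not samples:
        raise ValueError("refusing to write an empty dataset")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True to replace its contents")
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        paths = []
        for j, img in enumerate(s.images):
            rel = f"images/{s.patient_id}_{j}.png"
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / rel)
            paths.append(rel)
        rows.append({
            "patient_id": s.patient_id,
            "images": "|".join(paths),
            "report": " ".join(s.report),
            "labels": "|".join(str(int(v)) for v in s.labels),
        })
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    return out
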