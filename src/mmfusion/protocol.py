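"""The annotation-burden experiment protocol.

The dataset is partitioned into ``n`` patient-disjoint chunks (``n = 1, 2,
4``), emulating access to ``1/n`` of the labelled data.  Within each chunk,
patients are split 80/10/10 into train/validation/test so that all records of
one patient land in exactly one subset.  Every model variant is trained on each
chunk, the per-chunk test metrics are averaged over chunks, the whole procedure
is repeated (5 times by default) with fresh split and initialisation seeds, and
repeat means are averaged again (mean of means).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import metrics as mm_metrics
from .models import (ArchitectureConfig, FusionModel, FusionModelSpec,
                     LateFusionModel, build_model, transfer_pretrained_weights)
from .nn import (Adam, binary_cross_entropy, categorical_cross_entropy,
                 get_dtype, get_weights, set_weights, step_decay_schedule)
from .synthetic import MultimodalSample
from .text import build_vocabulary, encode_report, train_skipgram


# ---------------------------------------------------------------------------
# dataset loading (counterpart of synthetic.write_dataset)
# ---------------------------------------------------------------------------

def load_dataset(data_dir: str | Path) -> list[MultimodalSample]:
    """Read a dataset directory (PNG images + metadata.csv) back into samples."""
    root = Path(data_dir)
    meta = pd.read_csv(root / "metadata.csv", keep_default_na=False,
                       dtype={"patient_id": str, "images": str,
                              "report": str, "labels": str})
    samples = []
    for row in meta.itertuples(index=False):
        images = [np.asarray(Image.open(root / p), dtype=np.float64) / 255.0
                  for p in row.images.split("|")]
        report = row.report.split() if row.report else []
        labels = np.array([int(v) for v in row.labels.split("|")], dtype=np.int64)
        samples.append(MultimodalSample(row.patient_id, images, report, labels))
    return samples


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-exclusive train/validation/test assignment for one partition."""

    train: set[str]
    val: set[str]
    test: set[str]
    seed: int
    partition_index: int = 0
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise ValueError("train/val/test patient sets must be disjoint")


def partition_dataset(samples: list[MultimodalSample], n: int,
                      seed: int = 0) -> list[list[MultimodalSample]]:
    """Shuffle patients and deal them into n near-equal partitions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pids = sorted({s.patient_id for s in samples})
    if n > len(pids):
        raise ValueError(f"cannot make {n} partitions from {len(pids)} patients")
    rng = np.random.default_rng(seed)
    order = [pids[i] for i in rng.permutation(len(pids))]
    assign = {pid: i % n for i, pid in enumerate(order)}
    parts: list[list[MultimodalSample]] = [[] for _ in range(n)]
    for s in samples:
        parts[assign[s.patient_id]].append(s)
    return parts


def make_split(partition: list[MultimodalSample],
               fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0, partition_index: int = 0,
               repeat_index: int = 0) -> SplitPlan:
    """Greedy patient-level split hitting the sample-count fractions within
    one patient's worth of records."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_pid: dict[str, int] = {}
    for s in partition:
        by_pid[s.patient_id] = by_pid.get(s.patient_id, 0) + len(s.images)
    pids = sorted(by_pid)
    if len(pids) < 3:
        raise ValueError("a split needs at least 3 patients")
    rng = np.random.default_rng(seed)
    order = [pids[i] for i in rng.permutation(len(pids))]
    total = sum(by_pid.values())
    cut1, cut2 = fractions[0] * total, (fractions[0] + fractions[1]) * total
    train, val, test = [], [], []
    cum = 0.0
    for pid in order:
        if cum < cut1:
            train.append(pid)
        elif cum < cut2:
            val.append(pid)
        else:
            test.append(pid)
        cum += by_pid[pid]
    # guarantee non-empty validation and test sets
    for bucket in (val, test):
        if not bucket and len(train) > 1:
            bucket.append(train.pop())
    return SplitPlan(set(train), set(val), set(test), seed=seed,
                     partition_index=partition_index, repeat_index=repeat_index)


def compute_class_weights(labels: np.ndarray, max_weight: float = 50.0) -> np.ndarray:
    """Inverse-frequency positive-class weights: N / (n_classes * positives_c).

    Classes with zero positives get ``max_weight`` with a warning.
    """
    y = np.asarray(labels)
    n, k = y.shape
    pos = y.sum(axis=0).astype(float)
    weights = np.full(k, float(max_weight))
    nonzero = pos > 0
    weights[nonzero] = n / (k * pos[nonzero])
    if not np.all(nonzero):
        missing = np.flatnonzero(~nonzero).tolist()
        warnings.warn(f"classes {missing} have no positive training labels; "
                      f"weight capped at {max_weight}")
    return np.minimum(weights, max_weight)


# ---------------------------------------------------------------------------
# training configuration and feature preparation
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of a single training run.

    Defaults are the full-scale values (80 epochs, batch 8, Adam with a
    stepped learning rate, dropout 0.5, horizontal flips at p=0.5);
    :meth:`desk_scale` returns the CPU-scale configuration used throughout the
    test suite.
    """

    epochs: int = 80
    batch_size: int = 8
    lr: float = 1e-3
    hflip_prob: float = 0.5
    dropout: float = 0.5
    loss: str = "auto"  # auto | categorical_cross_entropy | binary_cross_entropy
    class_weight_max: float = 50.0
    embed_dim: int = 224
    text_len: int = 200
    sg_window: int = 5
    sg_epochs: int = 5
    sg_min_count: int = 1
    whole_corpus_embeddings: bool = False
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        base = dict(epochs=20, batch_size=8, embed_dim=32, text_len=24,
                    sg_window=4, sg_epochs=3,
                    arch=ArchitectureConfig(wide_filters=32, fc_dims=(64, 32)))
        base.update(overrides)
        return cls(**base)

    def resolve_loss(self, head: str) -> str:
        expected = ("categorical_cross_entropy" if head == "softmax_cce"
                    else "binary_cross_entropy")
        if self.loss not in ("auto", expected):
            raise ValueError(f"loss {self.loss!r} does not match head {head!r}")
        return expected


@dataclass
class PreparedSplit:
    """Per-split model-ready arrays; one record per patient-image."""

    X_img: dict[str, np.ndarray]   # subset -> (M, H, W)
    X_txt: dict[str, np.ndarray]   # subset -> (M, L, d)
    Y: dict[str, np.ndarray]       # subset -> (M, n_classes)
    pids: dict[str, list[str]]
    plan: SplitPlan
    text_range: tuple[float, float]


def _flatten(samples: list[MultimodalSample]) -> list[tuple[str, np.ndarray, list[str], np.ndarray]]:
    return [(s.patient_id, img, s.report, s.labels)
            for s in samples for img in s.images]


def prepare_split(partition: list[MultimodalSample], plan: SplitPlan,
                  config: TrainConfig, embed_seed: int = 0) -> PreparedSplit:
    """Train embeddings and encode a partition's records for one split.

    Skip-gram embeddings are trained on the training subset's reports only
    (no text leakage), unless ``config.whole_corpus_embeddings`` mirrors
    whole-corpus training.  Text matrices are min-max rescaled to [0, 1] using
    the training subset's range, so text blocks share the image intensity
    scale for early fusion.
    """
    subsets = {"train": plan.train, "val": plan.val, "test": plan.test}
    by_subset = {k: [s for s in partition if s.patient_id in v]
                 for k, v in subsets.items()}
    corpus_samples = partition if config.whole_corpus_embeddings else by_subset["train"]
    corpus = [s.report for s in corpus_samples]
    vocab = build_vocabulary(corpus, min_count=config.sg_min_count)
    emb = train_skipgram(corpus, d=config.embed_dim, window=config.sg_window,
                         epochs=config.sg_epochs, seed=embed_seed,
                         min_count=config.sg_min_count, vocab=vocab)

    encoded: dict[str, np.ndarray] = {}
    for s in partition:
        encoded[s.patient_id] = encode_report(s.report, emb, L_max=config.text_len)
    train_stack = np.stack([encoded[s.patient_id] for s in by_subset["train"]])
    mn, mx = float(train_stack.min()), float(train_stack.max())
    scale = (mx - mn) or 1.0

    dt = get_dtype()
    X_img, X_txt, Y, pids = {}, {}, {}, {}
    for k, subset in by_subset.items():
        recs = _flatten(subset)
        X_img[k] = np.stack([r[1] for r in recs]).astype(dt) if recs \
            else np.zeros((0, 1, 1), dtype=dt)
        X_txt[k] = np.clip(
            (np.stack([encoded[r[0]] for r in recs]) - mn) / scale,
            0.0, 1.0).astype(dt) \
            if recs else np.zeros((0, config.text_len, config.embed_dim), dtype=dt)
        Y[k] = np.stack([r[3] for r in recs]).astype(np.float64) \
            if recs else np.zeros((0, 1))
        pids[k] = [r[0] for r in recs]
    return PreparedSplit(X_img, X_txt, Y, pids, plan, (mn, mx))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _augment_images(x: np.ndarray, hflip_prob: float,
                    rng: np.random.Generator) -> np.ndarray:
    if hflip_prob <= 0.0 or x.size == 0:
        return x
    flip = rng.random(x.shape[0]) < hflip_prob
    if not flip.any():
        return x
    out = x.copy()
    out[flip] = out[flip, :, ::-1]
    return out


def _batch_loss(model: FusionModel, xi, xt, y, loss_name, class_weights,
                train: bool):
    x = model.make_input(xi, xt)
    logits = model.net.forward(x, train=train)
    if loss_name == "categorical_cross_entropy":
        return categorical_cross_entropy(logits, y, class_weights)
    return binary_cross_entropy(logits, y, class_weights)


def _eval_loss(model, prepared, subset, loss_name, class_weights,
               batch: int = 256) -> float:
    Xi, Xt, Y = prepared.X_img[subset], prepared.X_txt[subset], prepared.Y[subset]
    total, count = 0.0, 0
    for start in range(0, len(Y), batch):
        sl = slice(start, start + batch)
        loss, _ = _batch_loss(model, Xi[sl], Xt[sl], Y[sl], loss_name,
                              class_weights, train=False)
        total += loss * (min(start + batch, len(Y)) - start)
        count += min(start + batch, len(Y)) - start
    return total / max(count, 1)


def _train_single(model: FusionModel, prepared: PreparedSplit,
                  config: TrainConfig, seed: int) -> dict:
    loss_name = config.resolve_loss(model.spec.head)
    rng = np.random.default_rng(seed)
    Xi, Xt, Y = (prepared.X_img["train"], prepared.X_txt["train"],
                 prepared.Y["train"])
    class_weights = compute_class_weights(Y, max_weight=config.class_weight_max)
    uses_images = model.spec.model_name != "text_only"

    opt = Adam(model.net.params, lr=config.lr)
    lr_at = step_decay_schedule(config.lr, config.epochs)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, get_weights(model.net))
    m = len(Y)
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch)
        order = rng.permutation(m)
        epoch_loss, seen = 0.0, 0
        for start in range(0, m, config.batch_size):
            idx = order[start:start + config.batch_size]
            xi = Xi[idx]
            if uses_images:
                xi = _augment_images(xi, config.hflip_prob, rng)
            loss, dlogits = _batch_loss(model, xi, Xt[idx], Y[idx], loss_name,
                                        class_weights, train=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at epoch "
                    f"{epoch}, model {model.spec.name}")
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val_loss = _eval_loss(model, prepared, "val", loss_name, class_weights)
        history["train_loss"].append(epoch_loss / max(seen, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best[0]:
            best = (val_loss, get_weights(model.net))
    set_weights(model.net, best[1])  # best-validation-loss checkpoint
    history["best_val_loss"] = best[0]
    return history


def train_model(spec_or_model, prepared: PreparedSplit, config: TrainConfig,
                pretrained: tuple[FusionModel, FusionModel] | None = None):
    """Train one model variant on a prepared split.

    Accepts a :class:`FusionModelSpec` (a model is built from it) or an
    already-built model.  For ``spec.pretrained`` variants, ``pretrained``
    supplies the trained unimodal (image, text) models whose feature extractors
    initialise the fusion branches.  Returns ``(model, history)``.
    """
    if prepared.Y["train"].size == 0 or prepared.Y["val"].size == 0 \
            or prepared.Y["test"].size == 0:
        raise ValueError("degenerate split: every subset must be non-empty")
    if isinstance(spec_or_model, FusionModelSpec):
        spec = spec_or_model
        h, w = prepared.X_img["train"].shape[1:3]
        L, d = prepared.X_txt["train"].shape[1:3]
        model = build_model(spec, image_size=h, text_len=L, embed_dim=d,
                            arch=config.arch, seed=config.seed)
    else:
        model = spec_or_model
        spec = model.spec
    if spec.pretrained:
        if pretrained is None:
            raise ValueError("spec.pretrained requires trained unimodal models")
        transfer_pretrained_weights(pretrained[0], pretrained[1], model)

    if isinstance(model, LateFusionModel):
        rng = np.random.default_rng(config.seed)
        history = {
            "image": _train_single(model.image_model, prepared, config,
                                   seed=int(rng.integers(2**31))),
            "text": _train_single(model.text_model, prepared, config,
                                  seed=int(rng.integers(2**31))),
        }
    else:
        history = _train_single(model, prepared, config, seed=config.seed)
    return model, history


def evaluate_model(model, prepared: PreparedSplit, subset: str = "test",
                   batch: int = 256) -> dict[str, float]:
    """Test-set AUC, precision, recall and F1 for a trained model."""
    Xi, Xt, Y = prepared.X_img[subset], prepared.X_txt[subset], prepared.Y[subset]
    probs = np.concatenate([
        model.predict_proba(Xi[s:s + batch], Xt[s:s + batch])
        for s in range(0, len(Y), batch)])
    mode = "binary" if model.spec.head == "softmax_cce" else "multilabel"
    if mode == "binary":
        scores, labels = probs[:, 1], Y[:, 1].astype(int)
    else:
        scores, labels = probs, Y.astype(int)
    auc = mm_metrics.auc(scores, labels, mode=mode)
    precision, recall = mm_metrics.precision_recall(scores, labels)
    return {"auc": auc, "precision": precision, "recall": recall,
            "f1": mm_metrics.f1(precision, recall)}


# ---------------------------------------------------------------------------
# the full factorial experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Partition-level metric rows plus the mean-of-means aggregation."""

    runs: pd.DataFrame  # model, n, repeat, partition, auc, precision, recall, f1

    def aggregate(self) -> pd.DataFrame:
        """Mean over partitions within a repeat, then mean over repeats."""
        per_repeat = (self.runs
                      .groupby(["model", "n", "repeat"], as_index=False)
                      [["auc", "precision", "recall", "f1"]].mean())
        return (per_repeat.groupby(["model", "n"], as_index=False)
                [["auc", "precision", "recall", "f1"]].mean())


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_experiment(samples: list[MultimodalSample],
                   specs: list[FusionModelSpec],
                   ns: tuple[int, ...] = (1, 2, 4),
                   repeats: int = 5,
                   config: TrainConfig | None = None,
                   base_seed: int = 0,
                   log_path: str | Path | None = None) -> ExperimentResult:
    """Full factorial over specs x ns x repeats x partitions.

    Each repeat re-randomises both the partition/split seeds and the network
    initialisation seeds.  Within a split, unimodal models are trained first
    when any requested variant needs pretrained branch weights, and reused.
    """
    config = config or TrainConfig()
    log_fh = open(log_path, "a") if log_path else None
    rows = []
    try:
        for r in range(repeats):
            for n in ns:
                parts = partition_dataset(samples, n,
                                          seed=_derive_seed(base_seed, r, n, 0))
                for p_idx, part in enumerate(parts):
                    plan = make_split(part, seed=_derive_seed(base_seed, r, n, 1 + p_idx),
                                      partition_index=p_idx, repeat_index=r)
                    prepared = prepare_split(
                        part, plan, config,
                        embed_seed=_derive_seed(base_seed, r, n, 100 + p_idx))
                    uni_cache: dict[str, FusionModel] = {}

                    def _unimodal(kind: str, run_seed: int) -> FusionModel:
                        if kind not in uni_cache:
                            if kind == "image":
                                s = FusionModelSpec("image_only", "none", "square",
                                                    backbone=specs[0].backbone,
                                                    head=specs[0].head,
                                                    n_classes=specs[0].n_classes)
                            else:
                                s = FusionModelSpec("text_only", "wide", "none",
                                                    backbone=specs[0].backbone,
                                                    head=specs[0].head,
                                                    n_classes=specs[0].n_classes)
                            cfg = replace(config, seed=run_seed)
                            uni_cache[kind], _ = train_model(s, prepared, cfg)
                        return uni_cache[kind]

                    for s_idx, spec in enumerate(specs):
                        run_seed = _derive_seed(base_seed, r, n, p_idx, s_idx)
                        cfg = replace(config, seed=run_seed)
                        pre = None
                        if spec.pretrained:
                            pre = (_unimodal("image", _derive_seed(run_seed, 1)),
                                   _unimodal("text", _derive_seed(run_seed, 2)))
                        t0 = time.time()
                        model, _ = train_model(spec, prepared, cfg, pretrained=pre)
                        if spec.model_name == "image_only":
                            uni_cache.setdefault("image", model)
                        if spec.model_name == "text_only":
                            uni_cache.setdefault("text", model)
                        m = evaluate_model(model, prepared)
                        row = {"model": spec.name, "n": n, "repeat": r,
                               "partition": p_idx, **m}
                        rows.append(row)
                        if log_fh:
                            log_fh.write(json.dumps(
                                {**row, "seconds": round(time.time() - t0, 2),
                                 "seed": run_seed}) + "\n")
                            log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()
    return ExperimentResult(pd.DataFrame(rows))
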