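"""Text pipeline: vocabulary indexing, skip-gram embeddings, report encoding.

Reports are converted to fixed-size matrices for the fusion models: each of the
first ``L_max`` tokens contributes its embedding vector as one row, shorter
reports are padded with the padding vector, and out-of-vocabulary tokens map to
a dedicated OOV vector.  At full scale a report becomes a 200x224 matrix so
that the text block can be stacked under a 224-wide image for early fusion.

Embeddings are trained with skip-gram and negative sampling on the corpus
itself (no pretrained vectors), matching the preference of skip-gram for
infrequent words in small domain corpora.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop empty tokens."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """1-of-K token index with reserved padding and OOV slots.

    Real tokens occupy dense indices ``[0, size)`` ordered by descending
    frequency (ties broken lexicographically); ``pad_index == size`` and
    ``oov_index == size + 1``.
    """

    token_to_index: dict[str, int]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    @property
    def pad_index(self) -> int:
        return self.size

    @property
    def oov_index(self) -> int:
        return self.size + 1

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, self.oov_index)

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\t{self.counts.get(tok, 0)}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        tok2idx, counts = {}, {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                tok, idx, cnt = line.rstrip("\n").split("\t")
                tok2idx[tok] = int(idx)
                counts[tok] = int(cnt)
        return cls(tok2idx, counts)


def build_vocabulary(corpus: list[list[str]], min_count: int = 1) -> Vocabulary:
    """Index every token with frequency >= min_count; deterministic order."""
    if not corpus or all(len(doc) == 0 for doc in corpus):
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts = Counter(tok for doc in corpus for tok in doc)
    kept = [t for t, c in counts.items() if c >= min_count]
    kept.sort(key=lambda t: (-counts[t], t))
    return Vocabulary({t: i for i, t in enumerate(kept)},
                      {t: counts[t] for t in kept})


@dataclass
class EmbeddingModel:
    """K x d learned vectors plus derived padding (zeros) and OOV (mean) rows."""

    vocab: Vocabulary
    vectors: np.ndarray  # (K, d)
    window: int
    epochs: int
    min_count: int
    seed: int

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def pad_vector(self) -> np.ndarray:
        return np.zeros(self.dim)

    @property
    def oov_vector(self) -> np.ndarray:
        return self.vectors.mean(axis=0)

    def lookup(self, token: str) -> np.ndarray:
        idx = self.vocab.index(token)
        if idx == self.vocab.oov_index:
            return self.oov_vector
        return self.vectors[idx]

    def save_word2vec(self, path: str | Path) -> None:
        """Persist in the word2vec text format (header 'K d', one token/line)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.vocab.size} {self.dim}\n")
            order = sorted(self.vocab.token_to_index.items(), key=lambda kv: kv[1])
            for tok, idx in order:
                vec = " ".join(f"{v:.8g}" for v in self.vectors[idx])
                fh.write(f"{tok} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            k, d = map(int, fh.readline().split())
            tok2idx: dict[str, int] = {}
            vectors = np.zeros((k, d))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                tok2idx[parts[0]] = i
                vectors[i] = [float(v) for v in parts[1:]]
        return cls(Vocabulary(tok2idx), vectors, window=0, epochs=0,
                   min_count=0, seed=0)


def train_skipgram(corpus: list[list[str]], d: int = 224, window: int = 5,
                   epochs: int = 5, seed: int = 0, min_count: int = 1,
                   negatives: int = 5, lr: float = 0.025,
                   vocab: Vocabulary | None = None) -> EmbeddingModel:
    """Skip-gram with negative sampling, trained single-threaded in NumPy.

    Deterministic for a fixed seed.  Negative-sampling distribution is the
    unigram distribution raised to 3/4, the standard choice.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    vocab = vocab or build_vocabulary(corpus, min_count=min_count)
    if vocab.size < 2:
        raise ValueError("skip-gram needs at least 2 distinct in-vocabulary tokens")
    rng = np.random.default_rng(seed)
    k = vocab.size

    # (center, context) pairs over in-vocabulary tokens only
    centers, contexts = [], []
    for doc in corpus:
        ids = [vocab.token_to_index[t] for t in doc if t in vocab.token_to_index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise ValueError("corpus yields no skip-gram training pairs")
    centers = np.asarray(centers)
    contexts = np.asarray(contexts)

    freq = np.zeros(k)
    for tok, cnt in vocab.counts.items():
        freq[vocab.token_to_index[tok]] = cnt
    if freq.sum() == 0:
        freq[:] = 1.0
    neg_p = freq ** 0.75
    neg_p /= neg_p.sum()

    w_in = rng.uniform(-0.5 / d, 0.5 / d, size=(k, d))
    w_out = np.zeros((k, d))
    n_pairs = len(centers)
    batch = 512
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            idx = order[start:start + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(k, size=(len(idx), negatives), p=neg_p)
            cur_lr = lr * max(1e-4, 1.0 - step / total_steps)
            step += 1

            vc = w_in[c]                                   # (B, d)
            vo = w_out[o]                                  # (B, d)
            vn = w_out[neg]                                # (B, neg, d)
            g_pos = _sigmoid((vc * vo).sum(1)) - 1.0       # (B,)
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", vc, vn))  # (B, neg)

            d_c = g_pos[:, None] * vo + np.einsum("bn,bnd->bd", g_neg, vn)
            np.add.at(w_in, c, -cur_lr * d_c)
            np.add.at(w_out, o, -cur_lr * g_pos[:, None] * vc)
            np.add.at(w_out, neg.ravel(),
                      (-cur_lr * g_neg[..., None] * vc[:, None, :]).reshape(-1, d))
    return EmbeddingModel(vocab, w_in, window=window, epochs=epochs,
                          min_count=min_count, seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def encode_report(tokens: list[str], embeddings: EmbeddingModel,
                  L_max: int = 200) -> np.ndarray:
    """Encode one report as an (L_max, d) matrix.

    Rows 0..min(len, L_max)-1 are the tokens' vectors in order; longer reports
    are truncated to the first L_max tokens; remaining rows are the padding
    vector.
    """
    out = np.tile(embeddings.pad_vector, (L_max, 1))
    for i, tok in enumerate(tokens[:L_max]):
        out[i] = embeddings.lookup(tok)
    return out
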