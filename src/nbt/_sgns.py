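"""Minimal skip-gram negative-sampling (SGNS) trainer for walk corpora.

A small, deterministic word2vec-style trainer tailored to graph-walk
vocabularies: skip-gram objective with negative sampling, unigram^0.75
noise distribution, linear learning-rate decay, and the classic per-pair
sequential SGD inner loop (numba-compiled, single-threaded). Given a fixed
seed the trained vectors are bit-reproducible.
"""

from __future__ import annotations

import math

import numba
import numpy as np

from .exceptions import ValidationError

__all__ = ["train_sgns"]


def _skipgram_pairs(corpus_idx: list[np.ndarray], window: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for sent in corpus_idx:
        n = len(sent)
        for off in range(1, window + 1):
            if n <= off:
                continue
            # symmetric pairs (i, i+off) in both directions
            left, right = sent[:-off], sent[off:]
            centers.append(left)
            contexts.append(right)
            centers.append(right)
            contexts.append(left)
    if not centers:
        raise ValidationError("corpus yields no skip-gram pairs")
    return np.concatenate(centers), np.concatenate(contexts)


@numba.njit(cache=False)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@numba.njit(cache=False, fastmath=True)
def _sgd_epoch(w_in, w_out, centers, contexts, order, noise_cdf,
               k_neg, lr0, lr1):  # pragma: no cover - exercised via train_sgns
    n_pairs = order.shape[0]
    d = w_in.shape[1]
    buf = np.empty(d, dtype=np.float32)
    denom = max(1, n_pairs - 1)
    for n in range(n_pairs):
        i = order[n]
        c = centers[i]
        lr = lr0 + (lr1 - lr0) * (n / denom)
        for j in range(d):
            buf[j] = 0.0
        for k in range(k_neg + 1):
            if k == 0:
                tgt = contexts[i]
                label = 1.0
            else:
                tgt = np.searchsorted(noise_cdf, np.random.random())
                label = 0.0
            s = 0.0
            for j in range(d):
                s += w_in[c, j] * w_out[tgt, j]
            if s > 8.0:
                f = 1.0
            elif s < -8.0:
                f = 0.0
            else:
                f = 1.0 / (1.0 + math.exp(-s))
            g = (label - f) * lr
            for j in range(d):
                buf[j] += g * w_out[tgt, j]
                w_out[tgt, j] += g * w_in[c, j]
        for j in range(d):
            w_in[c, j] += buf[j]


def train_sgns(corpus: list[list[str]], vector_size: int = 256, window: int = 4,
               negative: int = 10, epochs: int = 50, lr_initial: float = 0.03,
               lr_final: float = 0.0007, seed: int = 0) -> dict[str, np.ndarray]:
    """Train SGNS embeddings on a sentence corpus; returns token -> input vector."""
    if not corpus:
        raise ValidationError("empty corpus")
    if lr_final >= lr_initial:
        raise ValidationError("lr_final must be smaller than lr_initial")
    vocab = sorted({tok for sent in corpus for tok in sent})
    tok2idx = {t: i for i, t in enumerate(vocab)}
    nv = len(vocab)

    counts = np.zeros(nv)
    corpus_idx = []
    for sent in corpus:
        idx = np.array([tok2idx[t] for t in sent], dtype=np.int64)
        np.add.at(counts, idx, 1)
        corpus_idx.append(idx)

    centers, contexts = _skipgram_pairs(corpus_idx, window)
    n_pairs = len(centers)

    # unigram^0.75 noise distribution, sampled by inverse CDF
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5, 0.5, size=(nv, vector_size)).astype(np.float32)
    w_in /= vector_size
    w_out = np.zeros((nv, vector_size), dtype=np.float32)

    # the numba kernel draws negatives from numba's own RNG; seed it per run
    _seed_kernel_rng(seed % 2**31)
    for epoch in range(epochs):
        lr0 = lr_initial + (lr_final - lr_initial) * epoch / epochs
        lr1 = lr_initial + (lr_final - lr_initial) * (epoch + 1) / epochs
        order = rng.permutation(n_pairs)
        _sgd_epoch(w_in, w_out, centers, contexts, order, noise_cdf,
                   negative, np.float32(lr0), np.float32(lr1))

    return {tok: w_in[i].astype(float).copy() for tok, i in tok2idx.items()}
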