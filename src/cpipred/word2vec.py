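"""Continuous bag-of-words (CBOW) word embeddings with negative sampling.

A compact word2vec trainer sufficient for protein 3-mer corpora: for each
center word the mean of its context input vectors predicts the center via a
logistic objective against ``negative`` noise words drawn from the
unigram^(3/4) distribution. Gradients update both the context input vectors
and the center/noise output vectors (plain SGD with a linearly decaying
learning rate, as in the reference word2vec implementation).

Training is deterministic for a fixed seed; ``workers`` is accepted for
configuration compatibility but training is single-threaded.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

__all__ = ["CBOWWordModel"]


class CBOWWordModel:
    """CBOW word-vector model.

    Parameters
    ----------
    vector_size : embedding dimension.
    window : max distance between center and context word.
    negative : number of noise words per center word.
    epochs : passes over the corpus.
    alpha, min_alpha : initial / final SGD learning rate (linear decay).
    min_count : discard words rarer than this.
    seed : RNG seed (initialisation, noise draws, window jitter).
    workers : accepted for API compatibility; training is serial.

    Attributes
    ----------
    vocab_ : dict mapping word -> row index.
    vectors_ : (n_words, vector_size) input embeddings (the word vectors).
    """

    def __init__(self, vector_size=100, window=5, negative=5, epochs=20,
                 alpha=0.05, min_alpha=1e-4, min_count=1, seed=0, workers=1):
        self.vector_size = vector_size
        self.window = window
        self.negative = negative
        self.epochs = epochs
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.min_count = min_count
        self.seed = seed
        self.workers = workers

    # -- helpers ----------------------------------------------------------
    def _build_vocab(self, corpus):
        counts = Counter(w for sent in corpus for w in sent)
        words = sorted(w for w, c in counts.items() if c >= self.min_count)
        self.vocab_ = {w: i for i, w in enumerate(words)}
        self.index_to_word_ = words
        freq = np.array([counts[w] for w in words], dtype=float)
        noise = freq ** 0.75
        self._noise_cdf = np.cumsum(noise / noise.sum())

    def _draw_noise(self, rng, k):
        u = rng.random(k)
        return np.searchsorted(self._noise_cdf, u)

    # -- API ---------------------------------------------------------------
    def fit(self, corpus: list[list[str]]) -> "CBOWWordModel":
        """Train on a corpus of tokenized documents."""
        corpus = [list(s) for s in corpus if s]
        if not corpus:
            raise ValueError("empty corpus")
        self._build_vocab(corpus)
        n_words = len(self.vocab_)
        if n_words == 0:
            raise ValueError("vocabulary empty after min_count pruning")
        rng = np.random.default_rng(self.seed)
        dim = self.vector_size
        # word2vec-style init: small uniform input vectors, zero outputs
        w_in = (rng.random((n_words, dim)) - 0.5) / dim
        w_out = np.zeros((n_words, dim))

        encoded = [np.array([self.vocab_[w] for w in s if w in self.vocab_])
                   for s in corpus]
        encoded = [s for s in encoded if s.size >= 2]
        if not encoded:
            raise ValueError("no document has >= 2 in-vocabulary words")

        total_steps = self.epochs * sum(s.size for s in encoded)
        step = 0
        for _epoch in range(self.epochs):
            for sent in encoded:
                n = sent.size
                # per-center reduced window, as in word2vec
                reduced = rng.integers(1, self.window + 1, size=n)
                for pos in range(n):
                    lr = max(
                        self.min_alpha,
                        self.alpha * (1.0 - step / max(total_steps, 1)),
                    )
                    step += 1
                    w = reduced[pos]
                    lo, hi = max(0, pos - w), min(n, pos + w + 1)
                    ctx = np.r_[sent[lo:pos], sent[pos + 1:hi]]
                    if ctx.size == 0:
                        continue
                    center = sent[pos]
                    h = w_in[ctx].mean(axis=0)
                    targets = np.r_[center, self._draw_noise(rng, self.negative)]
                    labels = np.zeros(targets.size)
                    labels[0] = 1.0
                    logits = w_out[targets] @ h
                    preds = 1.0 / (1.0 + np.exp(-logits))
                    g = (labels - preds) * lr
                    grad_h = g @ w_out[targets]
                    w_out[targets] += np.outer(g, h)
                    w_in[ctx] += grad_h / ctx.size
        self.vectors_ = w_in
        self.out_vectors_ = w_out
        return self

    def __contains__(self, word: str) -> bool:
        return word in self.vocab_

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors_[self.vocab_[word]]

    def mean_vector(self, words: list[str]) -> np.ndarray:
        """Mean of the vectors of the in-vocabulary words.

        Out-of-vocabulary words are skipped; raises if none remain.
        """
        idx = [self.vocab_[w] for w in words if w in self.vocab_]
        if not idx:
            raise ValueError("no in-vocabulary words: document outside feature space")
        return self.vectors_[idx].mean(axis=0)
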