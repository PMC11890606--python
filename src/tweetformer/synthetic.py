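"""Seeded generator of tweet-like labelled corpora.

Real health-tweet benchmarks cannot be redistributed, so the test bed is a
synthetic corpus with the same structural properties the model cares
about: short noisy documents, a Zipf-distributed background vocabulary,
class-dependent keyword signal (disjoint per-class marker words injected
with probability ``signal_strength``), plus the usual tweet noise — URLs,
emoji, hashtags/mentions, ALL-CAPS and elongated words, and novel
out-of-vocabulary strings at controllable rates. Marker sets are disjoint
across classes, so as ``signal_strength`` approaches 1 a Bayes-optimal
classifier approaches F1 = 1.

Also houses the frozen confusion-count worked examples from the published
error analysis of the architecture's benchmark runs, used as fixtures for
the evaluation module.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionCounts
from .preprocess import RawDocument, emoji_table

__all__ = ["SyntheticSpec", "generate_corpus", "marker_words", "benchmark_confusion_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus; everything flows from ``seed``."""

    n_docs: int = 2000
    n_classes: int = 2
    vocab_size: int = 500
    doc_length: tuple[int, int] = (5, 20)
    signal_strength: float = 0.9
    oov_rate: float = 0.1
    url_rate: float = 0.15
    emoji_rate: float = 0.15
    elongation_rate: float = 0.1
    caps_rate: float = 0.1
    n_markers_per_class: int = 5
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal_strength", "oov_rate", "url_rate", "emoji_rate", "elongation_rate", "caps_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_docs < self.n_classes:
            raise ValueError("n_docs must be >= n_classes")
        lo, hi = self.doc_length
        if lo < 1 or hi < lo:
            raise ValueError("doc_length range must be positive and ordered")
        if self.n_classes < 2 or self.vocab_size < 1:
            raise ValueError("need >= 2 classes and >= 1 background word")


def _pseudoword(rng: np.random.Generator, lo: int = 3, hi: int = 8) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(string.ascii_lowercase), size=length))


def _background_vocab(rng: np.random.Generator, size: int) -> list[str]:
    words: dict[str, None] = {}
    while len(words) < size:
        words.setdefault(_pseudoword(rng))
    return list(words)


def _vocab_and_markers(spec: SyntheticSpec):
    rng = np.random.default_rng(spec.seed)
    background = _background_vocab(rng, spec.vocab_size)
    seen: set[str] = set(background)
    markers: list[list[str]] = []
    for _ in range(spec.n_classes):
        cls: list[str] = []
        while len(cls) < spec.n_markers_per_class:
            w = _pseudoword(rng)
            if w not in seen:
                cls.append(w)
                seen.add(w)
        markers.append(cls)
    return background, markers, seen, rng


def marker_words(spec: SyntheticSpec) -> list[list[str]]:
    """The per-class disjoint marker sets for a spec (deterministic)."""
    return _vocab_and_markers(spec)[1]


def generate_corpus(spec: SyntheticSpec) -> list[RawDocument]:
    """Draw ``spec.n_docs`` labelled raw documents, fully seeded."""
    background, markers, seen, rng = _vocab_and_markers(spec)
    # Zipf weights over ranked background words
    ranks = np.arange(1, spec.vocab_size + 1, dtype=np.float64)
    zipf = ranks ** (-spec.zipf_exponent)
    zipf /= zipf.sum()
    emoji_glyphs = list(emoji_table())
    lo, hi = spec.doc_length
    docs: list[RawDocument] = []
    for i in range(spec.n_docs):
        label = int(rng.integers(0, spec.n_classes))
        length = int(rng.integers(lo, hi + 1))
        words = list(rng.choice(background, size=length, p=zipf))
        if rng.random() < spec.signal_strength:
            k = int(rng.integers(1, 4))
            for w in rng.choice(markers[label], size=k):
                words.insert(int(rng.integers(0, len(words) + 1)), w)
        if rng.random() < spec.oov_rate:
            novel = _pseudoword(rng, 6, 10)
            while novel in seen:
                novel = _pseudoword(rng, 6, 10)
            words.insert(int(rng.integers(0, len(words) + 1)), novel)
        if rng.random() < spec.elongation_rate:
            j = int(rng.integers(0, len(words)))
            w = words[j]
            pos = int(rng.integers(0, len(w)))
            words[j] = w[:pos] + w[pos] * int(rng.integers(2, 5)) + w[pos:]
        if rng.random() < spec.caps_rate:
            j = int(rng.integers(0, len(words)))
            words[j] = words[j].upper()
        if rng.random() < 0.2:
            j = int(rng.integers(0, len(words)))
            words[j] = ("#" if rng.random() < 0.5 else "@") + words[j]
        if rng.random() < spec.url_rate:
            tail = "".join(rng.choice(list(string.ascii_lowercase + string.digits), size=8))
            words.insert(int(rng.integers(0, len(words) + 1)), f"https://t.co/{tail}")
        if rng.random() < spec.emoji_rate:
            words.insert(int(rng.integers(0, len(words) + 1)), str(rng.choice(emoji_glyphs)))
        docs.append(RawDocument(id=f"doc{i}", text=" ".join(words), label=label))
    return docs


def benchmark_confusion_fixtures() -> dict[str, ConfusionCounts]:
    """Frozen worked-example confusion counts from the published error analysis."""
    return {
        "smm4h18_task4": ConfusionCounts(tp=802, fp=183, fn=99),
        "smm4h17_task2": ConfusionCounts(tp=2854, fp=1013, fn=1241),
    }
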