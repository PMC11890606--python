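"""Word-level vocabulary with character n-gram fallback for unseen words.

The classifier uses a closed word vocabulary built from the training corpus.
Out-of-vocabulary words — endemic in tweets (typos, hashtag mashups, drug
names) — are decomposed into character subword units (n-grams of length 3–6
plus every single character seen at build time) by greedy longest-match
segmentation; the embedder later represents such a word as the *sum* of its
unit vectors. Because every single character is a unit, segmentation always
terminates with full coverage; characters never seen at all map to the
reserved unknown-unit id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .preprocess import CleanDocument

__all__ = ["Vocabulary", "TokenSequence", "build_vocab", "segment_oov", "encode"]

PAD_ID = 0
UNK_ID = 1

_VOCAB_HEADER = "tweetformer-vocab v1"
_NGRAM_RANGE = (3, 6)


@dataclass
class Vocabulary:
    """Word and subword-unit id maps.

    Id 0 is reserved for padding and id 1 for the unknown subword unit in
    *both* maps, so real entries start at 2 and word ids never collide with
    the padding id.
    """

    word_to_id: dict[str, int]
    subunit_to_id: dict[str, int]
    min_count: int = 1
    id_to_word: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.id_to_word = {i: w for w, i in self.word_to_id.items()}

    @property
    def n_words(self) -> int:
        return 2 + len(self.word_to_id)

    @property
    def n_subunits(self) -> int:
        return 2 + len(self.subunit_to_id)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {_VOCAB_HEADER} min_count={self.min_count}\n")
            fh.write("[words]\n")
            for word, idx in sorted(self.word_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{word}\t{idx}\n")
            fh.write("[subunits]\n")
            for unit, idx in sorted(self.subunit_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{unit}\t{idx}\n")

    @classmethod
    def load(cls, path: str) -> "Vocabulary":
        word_to_id: dict[str, int] = {}
        subunit_to_id: dict[str, int] = {}
        section = None
        min_count = 1
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if _VOCAB_HEADER not in header:
                raise ValueError(f"not a vocabulary file: {path}")
            min_count = int(header.rsplit("min_count=", 1)[1])
            for line in fh:
                line = line.rstrip("\n")
                if line == "[words]":
                    section = word_to_id
                elif line == "[subunits]":
                    section = subunit_to_id
                elif line:
                    key, idx = line.rsplit("\t", 1)
                    assert section is not None
                    section[key] = int(idx)
        return cls(word_to_id=word_to_id, subunit_to_id=subunit_to_id, min_count=min_count)


@dataclass
class TokenSequence:
    """One encoded document, padded/truncated to ``max_len``.

    ``oov_map`` holds, for each position whose word was out of vocabulary,
    the ordered subword-unit ids covering that word.
    """

    ids: np.ndarray  # (max_len,) int32
    mask: np.ndarray  # (max_len,) bool
    oov_map: dict[int, list[int]]
    label: Optional[int] = None

    @property
    def n_tokens(self) -> int:
        return int(self.mask.sum())


def _iter_texts(corpus: Iterable) -> Iterable[str]:
    for doc in corpus:
        yield doc.text if isinstance(doc, CleanDocument) else str(doc)


def build_vocab(corpus: Sequence, min_count: int = 1) -> Vocabulary:
    """Build word and subword-unit inventories from a normalized corpus.

    Words with frequency >= ``min_count`` get word ids. The subword
    inventory holds all character n-grams (length 3–6) with token-level
    frequency >= ``min_count``, plus every single character observed.
    Deterministic given corpus order (first occurrence fixes the id).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    word_counts: Counter[str] = Counter()
    word_order: dict[str, None] = {}
    for text in _iter_texts(corpus):
        for tok in text.split():
            word_counts[tok] += 1
            word_order.setdefault(tok)

    ngram_counts: Counter[str] = Counter()
    ngram_order: dict[str, None] = {}
    lo, hi = _NGRAM_RANGE
    for word in word_order:
        reps = word_counts[word]
        for n in range(1, hi + 1):
            if n != 1 and not lo <= n <= hi:
                continue
            for i in range(len(word) - n + 1):
                gram = word[i : i + n]
                ngram_counts[gram] += reps
                ngram_order.setdefault(gram)

    word_to_id = {w: i for i, w in enumerate((w for w in word_order if word_counts[w] >= min_count), start=2)}
    kept = (g for g in ngram_order if len(g) == 1 or ngram_counts[g] >= min_count)
    subunit_to_id = {g: i for i, g in enumerate(kept, start=2)}
    return Vocabulary(word_to_id=word_to_id, subunit_to_id=subunit_to_id, min_count=min_count)


def segment_oov(word: str, vocab: Vocabulary) -> list[int]:
    """Greedy left-to-right longest-match segmentation into unit ids.

    Always covers the whole word: single characters are units, and any
    character outside the inventory yields the unknown-unit id.
    """
    if not word:
        raise ValueError("cannot segment an empty word")
    units: list[int] = []
    table = vocab.subunit_to_id
    i = 0
    max_n = _NGRAM_RANGE[1]
    while i < len(word):
        for n in range(min(max_n, len(word) - i), 0, -1):
            gram = word[i : i + n]
            if gram in table:
                units.append(table[gram])
                i += n
                break
        else:
            units.append(UNK_ID)
            i += 1
    return units


def encode(doc: CleanDocument, vocab: Vocabulary, max_len: int = 128) -> TokenSequence:
    """Map a normalized document to padded ids with OOV decompositions.

    Tokens beyond ``max_len`` are truncated from the right; shorter texts
    are padded with id 0 / mask ``False``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = doc.text.split()[:max_len]
    ids = np.zeros(max_len, dtype=np.int32)
    mask = np.zeros(max_len, dtype=bool)
    oov_map: dict[int, list[int]] = {}
    for pos, tok in enumerate(tokens):
        mask[pos] = True
        wid = vocab.word_to_id.get(tok)
        if wid is None:
            ids[pos] = UNK_ID
            oov_map[pos] = segment_oov(tok, vocab)
        else:
            ids[pos] = wid
    return TokenSequence(ids=ids, mask=mask, oov_map=oov_map, label=doc.label)
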