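"""Hybrid position + word embeddings.

Each token is represented by the end-to-end concatenation of a 300-d word
vector and a 300-d positional vector drawn from a fixed table of 128 rows
(one per admissible sentence position), giving a 600-d input row per token.
The same word at two positions therefore gets two different representations.
Out-of-vocabulary words are embedded as the elementwise sum of their
character-subword unit vectors.

Word and subunit tables are small-scale uniform random and trainable by
default; the positional table is random normal (scale 0.1) and frozen — it
encodes *where*, not *what*, and nothing in the model requires it to move.
A loader for word2vec text-format vectors can overwrite word rows with
pretrained values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tokenizer import PAD_ID, TokenSequence, Vocabulary

__all__ = ["EmbeddingTables", "init_tables", "word_vector", "embed_sequence", "load_word2vec_text"]


@dataclass
class EmbeddingTables:
    word_table: np.ndarray  # (V, dim)
    subunit_table: np.ndarray  # (S, dim)
    position_table: np.ndarray  # (max_len, dim)
    train_words: bool = True
    train_subunits: bool = True
    train_positions: bool = False
    seed: int = 0

    @property
    def dim(self) -> int:
        return self.word_table.shape[1]


def init_tables(
    vocab: Vocabulary,
    max_len: int = 128,
    dim: int = 300,
    seed: int = 0,
    dtype=np.float32,
) -> EmbeddingTables:
    """Seeded random initialization of all three tables.

    Word/subunit rows ~ U(-0.5/dim, 0.5/dim); position rows ~ 0.1·N(0, 1).
    The padding row (id 0) of the word table is zero and stays frozen.
    """
    if dim < 1 or max_len < 1:
        raise ValueError("dim and max_len must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 0.5 / dim
    word = rng.uniform(-scale, scale, size=(vocab.n_words, dim))
    subunit = rng.uniform(-scale, scale, size=(vocab.n_subunits, dim))
    position = 0.1 * rng.standard_normal(size=(max_len, dim))
    word[PAD_ID] = 0.0
    return EmbeddingTables(
        word_table=word.astype(dtype),
        subunit_table=subunit.astype(dtype),
        position_table=position.astype(dtype),
        seed=seed,
    )


def word_vector(seq: TokenSequence, pos: int, tables: EmbeddingTables) -> np.ndarray:
    """The word half of one token's representation.

    In-vocabulary tokens index the word table directly; OOV tokens sum the
    subunit-table rows of their character decomposition.
    """
    if not seq.mask[pos]:
        raise ValueError("padding has no word vector")
    if pos in seq.oov_map:
        return tables.subunit_table[seq.oov_map[pos]].sum(axis=0)
    return tables.word_table[seq.ids[pos]]


def embed_sequence(
    seq: TokenSequence,
    tables: EmbeddingTables,
    use_position_vector: bool = True,
) -> np.ndarray:
    """Full (max_len, 2·dim) input matrix for one sequence.

    Row t is ``[word_vector(t) ; position_table[t]]`` for real tokens and
    zero at padding. With ``use_position_vector=False`` (ablation) the word
    vector is duplicated so the output width is unchanged.
    """
    max_len = len(seq.ids)
    dim = tables.dim
    out = np.zeros((max_len, 2 * dim), dtype=tables.word_table.dtype)
    wordpart = tables.word_table[seq.ids]
    for pos, units in seq.oov_map.items():
        wordpart[pos] = tables.subunit_table[units].sum(axis=0)
    wordpart[~seq.mask] = 0.0
    out[:, :dim] = wordpart
    if use_position_vector:
        out[seq.mask, dim:] = tables.position_table[: max_len][seq.mask]
    else:
        out[:, dim:] = wordpart
    return out


def load_word2vec_text(path: str, vocab: Vocabulary, tables: EmbeddingTables) -> int:
    """Overwrite word rows with vectors from a word2vec text-format file.

    The file starts with ``"V dim"`` and then one ``word v1 … v_dim`` line
    per word. Words absent from the file keep their random rows. Returns
    the number of vocabulary words that received pretrained vectors.
    """
    loaded = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("not a word2vec text file: missing 'V dim' header")
        dim = int(header[1])
        if dim != tables.dim:
            raise ValueError(f"vector dim {dim} != table dim {tables.dim}")
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            word = parts[0]
            wid = vocab.word_to_id.get(word)
            if wid is not None:
                vec = np.asarray(parts[1 : dim + 1], dtype=np.float64)
                tables.word_table[wid] = vec.astype(tables.word_table.dtype)
                loaded += 1
    return loaded
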