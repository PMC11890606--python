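"""Tweet normalization pipeline.

Social-media text arrives full of HTML entities, links, emoji, hashtags,
ALL-CAPS shouting and elongated words ("soooo sick"). Before tokenization
every document passes through a fixed, deterministic sequence of cleanup
steps so that the downstream vocabulary stays small and the same surface
form always maps to the same token.

The normalized alphabet is ``{a-z, 0-9, space, underscore}``; underscores
only occur inside emoji description tokens such as ``thumbs_up``. Two
reserved tokens can be produced by the pipeline: ``url`` (for hyperlinks)
and ``number`` (for digit runs). ``normalize_text`` is idempotent — running
it on its own output changes nothing.
"""

from __future__ import annotations

import html
import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "RawDocument",
    "CleanDocument",
    "PreprocessConfig",
    "normalize_text",
    "normalize_document",
    "replace_urls",
    "replace_emojis",
    "emoji_table",
]

URL_TOKEN = "URL"
NUMBER_TOKEN = "number"

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_DIGIT_RUN_RE = re.compile(r"[0-9]+")
_elongation_re_cache: dict[int, re.Pattern] = {}


def _elongation_re(cap: int) -> re.Pattern:
    if cap not in _elongation_re_cache:
        _elongation_re_cache[cap] = re.compile(r"([a-z])\1{%d,}" % cap)
    return _elongation_re_cache[cap]
_NON_ALNUM_RE = re.compile(r"[^a-z0-9_ ]")
_WS_RE = re.compile(r"\s+")
# variation selectors and zero-width joiner, dropped before emoji lookup
_EMOJI_MODIFIER_RE = re.compile(r"[︀-️‍]")


@dataclass(frozen=True)
class RawDocument:
    """One unprocessed record: an id, the raw text, and an optional label."""

    id: str
    text: str
    label: Optional[int] = None


@dataclass(frozen=True)
class CleanDocument:
    """A normalized record; ``text`` is the output of :func:`normalize_text`."""

    id: str
    text: str
    label: Optional[int] = None


@dataclass(frozen=True)
class PreprocessConfig:
    """Switches for the optional readings of the normalization steps.

    replace_numbers
        Map every digit run to the reserved token ``number`` (default) or
        keep digits verbatim.
    caps_marker
        Prepend ``allcaps_`` to words that were fully upper-case in the raw
        text instead of silently lowercasing them.
    elongation_cap
        Maximum allowed consecutive repeats of one letter (default 2,
        i.e. "soooo" -> "soo").
    """

    replace_numbers: bool = True
    caps_marker: bool = False
    elongation_cap: int = 2


_DEFAULT_CONFIG = PreprocessConfig()

_EMOJI_TABLE: Optional[dict[str, str]] = None
_EMOJI_RE: Optional[re.Pattern] = None


def emoji_table() -> dict[str, str]:
    """The shipped emoji -> short-name mapping (a versioned package asset)."""
    global _EMOJI_TABLE
    if _EMOJI_TABLE is None:
        table: dict[str, str] = {}
        ref = importlib.resources.files("tweetformer") / "_data" / "emoji_names.tsv"
        for line in ref.read_text(encoding="utf-8").splitlines():
            if not line or line.startswith("#"):
                continue
            glyph, name = line.split("\t")
            table[glyph] = name
        _EMOJI_TABLE = table
    return _EMOJI_TABLE


def _emoji_pattern() -> re.Pattern:
    global _EMOJI_RE
    if _EMOJI_RE is None:
        # longest glyph sequences first so multi-codepoint entries win
        glyphs = sorted(emoji_table(), key=len, reverse=True)
        _EMOJI_RE = re.compile("|".join(re.escape(g) for g in glyphs))
    return _EMOJI_RE


def replace_urls(text: str) -> str:
    """Replace every maximal ``http(s)://...`` or ``www....`` span with ``URL``."""
    return _URL_RE.sub(URL_TOKEN, text)


def replace_emojis(text: str) -> str:
    """Replace each known emoji with its space-delimited textual short name.

    Variation selectors and zero-width joiners are stripped before lookup so
    that presentation variants of the same glyph normalize identically.
    Emoji absent from the shipped table are left untouched (they are dropped
    later by the non-alphanumeric step of the full pipeline).
    """
    text = _EMOJI_MODIFIER_RE.sub("", text)
    table = emoji_table()
    out: list[str] = []
    pos = 0
    for m in _emoji_pattern().finditer(text):
        before = text[pos : m.start()]
        out.append(before)
        if out and "".join(out) and not "".join(out).endswith(" "):
            out.append(" ")
        out.append(table[m.group(0)])
        pos = m.end()
        if pos < len(text) and text[pos] != " ":
            out.append(" ")
    out.append(text[pos:])
    return "".join(out)


def _lowercase(text: str, config: PreprocessConfig) -> str:
    if not config.caps_marker:
        return text.lower()
    out = []
    for tok in text.split(" "):
        if len(tok) > 1 and tok.isalpha() and tok.isupper():
            out.append("allcaps_" + tok.lower())
        else:
            out.append(tok.lower())
    return " ".join(out)


def normalize_text(raw: str, config: PreprocessConfig = _DEFAULT_CONFIG) -> str:
    """Run the full eight-step normalization pipeline on one string.

    Order matters: URLs and emoji are rewritten to reserved/description
    tokens *before* the destructive steps (lowercasing, digit folding,
    punctuation removal), otherwise their surface forms could not survive.

    Steps: (1) HTML-entity unescape; (2) URL -> ``URL``; (3) emoji -> short
    name; (4) lowercase; (5) digit run -> ``number``; (6) cap letter
    elongation; (7) every remaining non-alphanumeric character becomes a
    space (underscores inside tokens are kept); (8) whitespace collapse.
    """
    text = html.unescape(raw)
    text = replace_urls(text)
    text = replace_emojis(text)
    text = _lowercase(text, config)
    if config.replace_numbers:
        text = _DIGIT_RUN_RE.sub(f" {NUMBER_TOKEN} ", text)
    text = _elongation_re(config.elongation_cap).sub("\\1" * config.elongation_cap, text)
    text = _NON_ALNUM_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    # underscores are legal only token-internally (emoji/caps markers)
    tokens = [tok.strip("_") for tok in text.split(" ")]
    return " ".join(tok for tok in tokens if tok)


def normalize_document(doc: RawDocument, config: PreprocessConfig = _DEFAULT_CONFIG) -> CleanDocument:
    return CleanDocument(id=doc.id, text=normalize_text(doc.text, config), label=doc.label)
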