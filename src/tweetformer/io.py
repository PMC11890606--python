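"""Dataset readers/writers.

Datasets are UTF-8 TSV with header ``id<TAB>text<TAB>label`` (the label
column may be absent for prediction inputs). Tweets can contain literal
tabs and newlines, so those are escaped as ``\\t`` and ``\\n`` inside the
text field; the round trip write(read(f)) is byte-identical for
well-formed files.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .preprocess import RawDocument

__all__ = ["read_dataset", "write_dataset", "DatasetFormatError"]


class DatasetFormatError(ValueError):
    """A malformed dataset row; the message names the line number."""


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(ch)
        i += 1
    return "".join(out)


def read_dataset(path: str, with_labels: bool = True, n_classes: Optional[int] = None) -> list[RawDocument]:
    """Read a TSV dataset; validates column counts and label values."""
    docs: list[RawDocument] = []
    expected = 3 if with_labels else 2
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "text"] or (with_labels and (len(header) < 3 or header[2] != "label")):
            raise DatasetFormatError(f"line 1: expected header id<TAB>text" + ("<TAB>label" if with_labels else ""))
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != expected:
                raise DatasetFormatError(f"line {lineno}: expected {expected} columns, found {len(cols)}")
            label: Optional[int] = None
            if with_labels:
                try:
                    label = int(cols[2])
                except ValueError:
                    raise DatasetFormatError(f"line {lineno}: label {cols[2]!r} is not an integer") from None
                if label < 0 or (n_classes is not None and label >= n_classes):
                    raise DatasetFormatError(f"line {lineno}: label {label} outside [0, n_classes)")
            docs.append(RawDocument(id=cols[0], text=_unescape(cols[1]), label=label))
    return docs


def write_dataset(docs: Sequence[RawDocument], path: str, with_labels: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\ttext\tlabel\n" if with_labels else "id\ttext\n")
        for doc in docs:
            if with_labels:
                if doc.label is None:
                    raise ValueError(f"document {doc.id} has no label")
                fh.write(f"{doc.id}\t{_escape(doc.text)}\t{doc.label}\n")
            else:
                fh.write(f"{doc.id}\t{_escape(doc.text)}\n")
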