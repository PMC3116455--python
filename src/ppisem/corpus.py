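"""Corpus reading and sentence vectorisation.

Labelled sentences carry inline protein mentions and a binary
interaction label.  Preprocessing follows a fixed rule order: protein
mentions are replaced by per-sentence numbered placeholders, tokens are
lowercased, non-letter characters are stripped, stop words dropped, and
surviving tokens truncated to their first ten letters.  Placeholder
tokens bypass every filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._stopwords import DEFAULT_STOP_WORDS

PLACEHOLDER_PREFIX = "PTNGNE"
_PLACEHOLDER_RE = re.compile(r"^PTNGNE\d+$")
_NON_LETTER_RE = re.compile(r"[^a-z]+")

TRUNCATE_LEN = 10


class CorpusError(ValueError):
    """Malformed corpus input."""


class SpanConflictError(CorpusError):
    """Overlapping or out-of-bounds protein spans."""


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence with protein mention spans and a binary PPI label."""

    sentence_id: str
    abstract_id: str
    raw_text: str
    protein_spans: tuple[tuple[int, int], ...]
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise CorpusError(f"label must be 0 or 1, got {self.label!r}")
        n = len(self.raw_text)
        spans = sorted(self.protein_spans)
        for (a, b) in spans:
            if not (0 <= a < b <= n):
                raise SpanConflictError(
                    f"span ({a},{b}) outside text bounds [0,{n}) in "
                    f"sentence {self.sentence_id}"
                )
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 < b1:
                raise SpanConflictError(
                    f"overlapping protein spans in sentence {self.sentence_id}"
                )


@dataclass(frozen=True)
class Vocabulary:
    """Bijection token -> contiguous feature index, lexicographically ordered."""

    feature_to_index: dict[str, int]

    def __len__(self) -> int:
        return len(self.feature_to_index)

    @property
    def n_features(self) -> int:
        return len(self.feature_to_index)

    @property
    def index_to_feature(self) -> list[str]:
        inv = [""] * len(self.feature_to_index)
        for tok, i in self.feature_to_index.items():
            inv[i] = tok
        return inv

    def __contains__(self, token: str) -> bool:
        return token in self.feature_to_index

    def __getitem__(self, token: str) -> int:
        return self.feature_to_index[token]


@dataclass
class DocumentTermMatrix:
    """M x N matrix of raw token counts over a fixed vocabulary."""

    X: np.ndarray
    row_ids: list[str]
    vocabulary: Vocabulary = field(repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise CorpusError("count matrix must be 2-D")
        if self.X.shape != (len(self.row_ids), len(self.vocabulary)):
            raise CorpusError(
                f"shape {self.X.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.vocabulary)} features"
            )


def is_placeholder(token: str) -> bool:
    return _PLACEHOLDER_RE.match(token) is not None


def tokenize(
    raw_text: str, stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS
) -> list[str]:
    """Whitespace-split and normalise; placeholders pass through untouched.

    Rule order: lowercase -> strip non-letters -> drop empties -> drop stop
    words -> truncate to ``TRUNCATE_LEN`` letters.
    """
    out: list[str] = []
    for piece in raw_text.split():
        if is_placeholder(piece):
            out.append(piece)
            continue
        tok = _NON_LETTER_RE.sub("", piece.lower())
        if not tok or tok in stop_words:
            continue
        out.append(tok[:TRUNCATE_LEN])
    return out


def anonymize_proteins(sentence: LabeledSentence) -> str:
    """Replace the i-th protein mention (left to right, 1-based) by PTNGNE<i>."""
    spans = sorted(sentence.protein_spans)
    text = sentence.raw_text
    # replace right-to-left so earlier offsets stay valid
    for i in range(len(spans) - 1, -1, -1):
        a, b = spans[i]
        text = text[:a] + f"{PLACEHOLDER_PREFIX}{i + 1}" + text[b:]
    return text


def preprocess(
    sentence: LabeledSentence,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
) -> list[str]:
    """Anonymise then tokenise — the full per-sentence preprocessing path."""
    return tokenize(anonymize_proteins(sentence), stop_words)


def build_vocabulary(token_sequences: list[list[str]]) -> Vocabulary:
    """Index every unique token, lexicographically, for reproducible runs."""
    uniq: set[str] = set()
    for seq in token_sequences:
        uniq.update(seq)
    if not uniq:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    return Vocabulary({tok: i for i, tok in enumerate(sorted(uniq))})


def vectorize(
    token_sequences: list[list[str]],
    vocab: Vocabulary,
    row_ids: list[str] | None = None,
) -> DocumentTermMatrix:
    """Count in-vocabulary tokens per sentence; OOV tokens are ignored."""
    M, N = len(token_sequences), len(vocab)
    X = np.zeros((M, N), dtype=np.int64)
    f2i = vocab.feature_to_index
    for m, seq in enumerate(token_sequences):
        for tok in seq:
            j = f2i.get(tok)
            if j is not None:
                X[m, j] += 1
    if row_ids is None:
        row_ids = [str(m) for m in range(M)]
    return DocumentTermMatrix(X, list(row_ids), vocab)


# ---------------------------------------------------------------------------
# corpus file dialects
# ---------------------------------------------------------------------------

_PROT_OPEN = "<prot>"
_PROT_CLOSE = "</prot>"


def _parse_inline_text(tagged: str, lineno: int) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Strip <prot>...</prot> markup, returning plain text and mention spans."""
    text_parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    out_len = 0
    open_start: int | None = None
    token_re = re.compile(re.escape(_PROT_OPEN) + "|" + re.escape(_PROT_CLOSE))
    for m in token_re.finditer(tagged):
        chunk = tagged[pos : m.start()]
        text_parts.append(chunk)
        out_len += len(chunk)
        if m.group() == _PROT_OPEN:
            if open_start is not None:
                raise CorpusError(f"line {lineno}: nested <prot> tag")
            open_start = out_len
        else:
            if open_start is None:
                raise CorpusError(f"line {lineno}: </prot> without opening tag")
            spans.append((open_start, out_len))
            open_start = None
        pos = m.end()
    if open_start is not None:
        raise CorpusError(f"line {lineno}: unclosed <prot> tag")
    chunk = tagged[pos:]
    text_parts.append(chunk)
    return "".join(text_parts), tuple(spans)


def _render_inline_text(sentence: LabeledSentence) -> str:
    text = sentence.raw_text
    for a, b in sorted(sentence.protein_spans, reverse=True):
        text = text[:a] + _PROT_OPEN + text[a:b] + _PROT_CLOSE + text[b:]
    return text


def read_labeled_corpus(path: str, dialect: str = "inline-tag") -> list[LabeledSentence]:
    """Read a labelled corpus file.

    ``inline-tag``: tab-separated ``abstract_id<TAB>label<TAB>text`` where
    protein mentions are wrapped in ``<prot>...</prot>``.
    ``tabular``: same layout but the text already contains PTNGNE
    placeholders and carries no markup.
    """
    if dialect not in ("inline-tag", "tabular"):
        raise CorpusError(f"unknown corpus dialect {dialect!r}")
    sentences: list[LabeledSentence] = []
    per_abstract: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 2)
            if len(parts) != 3:
                raise CorpusError(
                    f"line {lineno}: expected abstract_id<TAB>label<TAB>text"
                )
            abstract_id, label_str, text = parts
            try:
                label = int(label_str)
            except ValueError as exc:
                raise CorpusError(f"line {lineno}: bad label {label_str!r}") from exc
            if label not in (0, 1):
                raise CorpusError(f"line {lineno}: label must be 0 or 1")
            if dialect == "inline-tag":
                raw_text, spans = _parse_inline_text(text, lineno)
            else:
                raw_text, spans = text, ()
            idx = per_abstract.get(abstract_id, 0)
            per_abstract[abstract_id] = idx + 1
            sentences.append(
                LabeledSentence(
                    sentence_id=f"{abstract_id}.{idx}",
                    abstract_id=abstract_id,
                    raw_text=raw_text,
                    protein_spans=spans,
                    label=label,
                )
            )
    return sentences


def write_labeled_corpus(
    path: str, sentences: list[LabeledSentence], dialect: str = "inline-tag"
) -> None:
    if dialect not in ("inline-tag", "tabular"):
        raise CorpusError(f"unknown corpus dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            if dialect == "inline-tag":
                text = _render_inline_text(s)
            else:
                text = anonymize_proteins(s)
            if "\t" in text or "\n" in text:
                raise CorpusError(
                    f"sentence {s.sentence_id}: text contains tab/newline"
                )
            fh.write(f"{s.abstract_id}\t{s.label}\t{text}\n")


def read_unlabeled_corpus(path: str) -> list[list[str]]:
    """Plain-text unlabelled corpus: one sentence per line, blank lines
    separate documents.  Returns raw whitespace token sequences (not yet
    normalised)."""
    sentences: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                sentences.append(line.split())
    return sentences


def write_unlabeled_corpus(path: str, sentences: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sentences:
            fh.write(" ".join(seq) + "\n")
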