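"""Sentence splitting, entity projection, candidate-pair enumeration and
entity marking.

The classifier consumes one marked sentence per candidate chemical-gene
pair: the two argument mentions are wrapped (or replaced) by marker tokens
while every other mention in the sentence is left as raw text.  Relations
are within-sentence only, so candidates are the cartesian product of the
chemical and gene mentions projected into each sentence window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

from .formats_io import Document, EntityMention, GoldRelation, RelationLabel

#: A splitter maps document text to ordered (start, end) offset pairs.
Splitter = Callable[[str], Sequence[tuple[int, int]]]


class MarkingMethod(Enum):
    """The four entity-marking strategies for rendering input sequences."""

    NONE = "none"  # original string, no markers
    MASK = "mask"  # entity replaced by its type marker
    WRAP_TYPE = "wrap_type"  # same marker before and after the entity
    WRAP_TYPE_SE = "wrap_type_se"  # distinct start/end markers per type


@dataclass(frozen=True)
class MarkerVocab:
    """Marker token strings; all are registered with the classifier as
    atomic vocabulary items."""

    chem_start: str = "CHEM-S"
    chem_end: str = "CHEM-E"
    gene_start: str = "GENE-S"
    gene_end: str = "GENE-E"
    chem_mask: str = "CHEM"
    gene_mask: str = "GENE"

    def tokens(self, method: "MarkingMethod") -> tuple[str, ...]:
        if method is MarkingMethod.MASK:
            return (self.chem_mask, self.gene_mask)
        if method is MarkingMethod.WRAP_TYPE:
            return (self.chem_mask, self.gene_mask)
        if method is MarkingMethod.WRAP_TYPE_SE:
            return (self.chem_start, self.chem_end, self.gene_start, self.gene_end)
        return ()


@dataclass
class SentenceWindow:
    """One sentence: a [start, end) slice of the document full text with the
    mentions fully contained in it."""

    pmid: str
    sent_index: int
    start: int
    end: int
    text: str
    mentions: list[EntityMention] = field(default_factory=list)

    def chemicals(self) -> list[EntityMention]:
        return [m for m in self.mentions if m.etype == "CHEMICAL"]

    def genes(self) -> list[EntityMention]:
        return [m for m in self.mentions if m.etype == "GENE"]


@dataclass(frozen=True)
class CandidatePair:
    """A chemical x gene mention pair inside one sentence."""

    pmid: str
    sent_index: int
    chem: EntityMention
    gene: EntityMention

    @property
    def pair_key(self) -> tuple[str, str, str]:
        return (self.pmid, self.chem.mention_id, self.gene.mention_id)


@dataclass(frozen=True)
class MarkedSequence:
    text: str
    method: MarkingMethod
    marker_vocab: tuple[str, ...] = ()


class SplitterContractError(ValueError):
    """A splitter returned overlapping, unordered or out-of-range windows."""


_SENTENCE_BOUNDARY = re.compile(
    r"""
    (?<=[.!?])          # sentence-final punctuation behind us
    \s+                 # the inter-sentence whitespace
    (?=[A-Z(\[\"'0-9])  # next sentence starts with capital/digit/bracket
    """,
    re.VERBOSE,
)


def rule_based_splitter(text: str) -> list[tuple[int, int]]:
    """Built-in rule-based sentence splitter.

    Splits at a tab (the title/abstract separator) and after sentence-final
    punctuation followed by whitespace and an uppercase/digit start.  Returns
    offset pairs trimmed of surrounding whitespace.  External splitters
    (e.g. a Stanza adapter) plug in through the same text -> offsets
    contract.
    """
    spans: list[tuple[int, int]] = []
    for chunk_start, chunk in _iter_tab_chunks(text):
        last = 0
        for m in _SENTENCE_BOUNDARY.finditer(chunk):
            spans.append((chunk_start + last, chunk_start + m.start()))
            last = m.end()
        if last < len(chunk):
            spans.append((chunk_start + last, chunk_start + len(chunk)))
    # trim whitespace from each span; drop empty spans
    trimmed = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


def _iter_tab_chunks(text: str) -> Iterable[tuple[int, str]]:
    pos = 0
    for part in text.split("\t"):
        yield pos, part
        pos += len(part) + 1


def split_sentences(
    doc: Document, splitter: Splitter = rule_based_splitter
) -> list[SentenceWindow]:
    """Split a document into sentence windows using a pluggable splitter.

    The returned windows are validated against the splitter contract: spans
    must be in-range, ordered and non-overlapping, and each window's text
    must equal the corresponding slice of ``full_text``.
    """
    full_text = doc.full_text
    spans = splitter(full_text)
    windows: list[SentenceWindow] = []
    prev_end = -1
    for i, (start, end) in enumerate(spans):
        if not (0 <= start < end <= len(full_text)):
            raise SplitterContractError(
                f"window {i} span [{start}, {end}) out of range for document "
                f"{doc.pmid} of length {len(full_text)}"
            )
        if start < prev_end:
            raise SplitterContractError(
                f"window {i} overlaps the previous window in document {doc.pmid}"
            )
        prev_end = end
        windows.append(
            SentenceWindow(
                pmid=doc.pmid,
                sent_index=i,
                start=start,
                end=end,
                text=full_text[start:end],
            )
        )
    return windows


@dataclass
class ProjectionReport:
    n_attached: int = 0
    n_dropped: int = 0  # mentions straddling a window boundary


def project_entities(
    doc: Document, windows: Sequence[SentenceWindow]
) -> ProjectionReport:
    """Attach each mention to the window that fully contains it.

    Mentions crossing a window boundary (or falling in dropped whitespace)
    are not attached; they are counted in the report rather than raised,
    since a splitter cannot always respect entity boundaries.
    """
    report = ProjectionReport()
    for m in doc.mentions:
        target = None
        for w in windows:
            if w.start <= m.start and m.end <= w.end:
                target = w
                break
        if target is None:
            report.n_dropped += 1
        else:
            target.mentions.append(m)
            report.n_attached += 1
    for w in windows:
        w.mentions.sort(key=lambda m: (m.start, m.end, m.mention_id))
    return report


def enumerate_pairs(window: SentenceWindow) -> list[CandidatePair]:
    """All chemical x gene mention pairs in one window, ordered by
    (chemical offset, gene offset)."""
    pairs = []
    for chem in window.chemicals():
        for gene in window.genes():
            pairs.append(
                CandidatePair(
                    pmid=window.pmid,
                    sent_index=window.sent_index,
                    chem=chem,
                    gene=gene,
                )
            )
    pairs.sort(key=lambda p: (p.chem.start, p.chem.end, p.gene.start, p.gene.end))
    return pairs


def candidate_pairs(doc: Document, splitter: Splitter = rule_based_splitter):
    """Convenience: split, project and enumerate in one pass."""
    windows = split_sentences(doc, splitter)
    project_entities(doc, windows)
    out: list[CandidatePair] = []
    for w in windows:
        out.extend(enumerate_pairs(w))
    return out


def mark_entities(
    window: SentenceWindow,
    pair: CandidatePair,
    method: MarkingMethod = MarkingMethod.WRAP_TYPE_SE,
    vocab: MarkerVocab = MarkerVocab(),
    max_sequence_chars: int | None = None,
) -> MarkedSequence:
    """Render the sentence with the candidate pair marked.

    Only the pair's two mentions are touched; co-occurring mentions stay as
    raw text.  For WRAP_TYPE_SE the original sentence is recoverable by
    deleting the four marker tokens and their padding spaces.  Overlapping
    spans are handled innermost-first; for identical spans the chemical
    markers go outside.
    """
    for m in (pair.chem, pair.gene):
        if not (window.start <= m.start and m.end <= window.end):
            raise ValueError(
                f"mention {m.mention_id} not contained in window "
                f"{window.pmid}#{window.sent_index}"
            )

    # window-relative spans
    cs, ce = pair.chem.start - window.start, pair.chem.end - window.start
    gs, ge = pair.gene.start - window.start, pair.gene.end - window.start
    text = window.text

    if method is MarkingMethod.NONE:
        out = text
    elif method is MarkingMethod.MASK:
        out = _replace_spans(
            text, [(cs, ce, vocab.chem_mask), (gs, ge, vocab.gene_mask)]
        )
    elif method in (MarkingMethod.WRAP_TYPE, MarkingMethod.WRAP_TYPE_SE):
        if method is MarkingMethod.WRAP_TYPE:
            c_open, c_close = vocab.chem_mask, vocab.chem_mask
            g_open, g_close = vocab.gene_mask, vocab.gene_mask
        else:
            c_open, c_close = vocab.chem_start, vocab.chem_end
            g_open, g_close = vocab.gene_start, vocab.gene_end
        # priority orders same-position insertions in the final string:
        # chemical markers outside when the spans coincide.
        chem_outer = (cs, ce) == (gs, ge) or (cs <= gs and ge <= ce)
        ins = [
            (cs, 0 if chem_outer else 1, c_open + " "),
            (gs, 1 if chem_outer else 0, g_open + " "),
            (ge, 0 if chem_outer else 1, " " + g_close),
            (ce, 1 if chem_outer else 0, " " + c_close),
        ]
        out = _insert_at(text, ins)
    else:  # pragma: no cover
        raise ValueError(f"unknown marking method {method!r}")

    if max_sequence_chars is not None and len(out) > max_sequence_chars:
        out = _truncate_around(
            out, min(cs, gs), max(ce, ge), max_sequence_chars
        )

    return MarkedSequence(text=out, method=method, marker_vocab=vocab.tokens(method))


def _replace_spans(text: str, repls: list[tuple[int, int, str]]) -> str:
    out = text
    for s, e, repl in sorted(repls, key=lambda r: r[0], reverse=True):
        out = out[:s] + repl + out[e:]
    return out


def _insert_at(text: str, insertions: list[tuple[int, int, str]]) -> str:
    """Insert strings at positions; (position, priority) ascending gives the
    left-to-right order in the final string."""
    parts: list[str] = []
    cursor = 0
    for pos, _prio, s in sorted(insertions, key=lambda t: (t[0], t[1])):
        parts.append(text[cursor:pos])
        parts.append(s)
        cursor = pos
    parts.append(text[cursor:])
    return "".join(parts)


def _truncate_around(text: str, lo: int, hi: int, cap: int) -> str:
    """Symmetric character truncation keeping the pair span centred."""
    span = hi - lo
    if span >= cap:
        return text[lo:hi]
    pad = (cap - span) // 2
    start = max(0, lo - pad)
    end = min(len(text), start + cap)
    start = max(0, end - cap)
    return text[start:end]


def unmark(marked: MarkedSequence) -> str:
    """Invert WRAP_TYPE_SE / WRAP_TYPE marking by deleting the marker tokens
    and their padding spaces."""
    if marked.method not in (MarkingMethod.WRAP_TYPE_SE, MarkingMethod.WRAP_TYPE):
        raise ValueError("only wrap-style markings are invertible")
    out = marked.text
    for tok in marked.marker_vocab:
        out = out.replace(tok + " ", "").replace(" " + tok, "")
    return out


def tag_with_gazetteer(
    doc: Document, gazetteer: dict[str, tuple[str, str]]
) -> list[EntityMention]:
    """Exact-match dictionary tagger for unlabelled text.

    ``gazetteer`` maps a surface form to (entity type, normalized id);
    matching is longest-match-first at word boundaries.  Intended for
    annotating weak-label pools from KB name dictionaries when no neural
    tagger output is available; spans already present on the document are
    not duplicated.
    """
    text = doc.full_text
    taken = [(m.start, m.end) for m in doc.mentions]
    found: list[EntityMention] = []
    counter = len(doc.mentions)
    for surface in sorted(gazetteer, key=len, reverse=True):
        etype, norm_id = gazetteer[surface]
        start = 0
        while True:
            idx = text.find(surface, start)
            if idx < 0:
                break
            start = idx + 1
            end = idx + len(surface)
            at_boundary = (idx == 0 or not text[idx - 1].isalnum()) and (
                end == len(text) or not text[end].isalnum()
            )
            overlaps = any(s < end and idx < e for s, e in taken)
            if at_boundary and not overlaps:
                counter += 1
                found.append(
                    EntityMention(
                        mention_id=f"G{counter}",
                        etype=etype,
                        start=idx,
                        end=end,
                        surface=surface,
                        norm_id=norm_id,
                    )
                )
                taken.append((idx, end))
    found.sort(key=lambda m: (m.start, m.end))
    return found


def label_candidates(
    pairs: Sequence[CandidatePair], relations: Iterable[GoldRelation]
) -> list[RelationLabel]:
    """Label each candidate pair with its gold relation type, or NONE.

    When a pair carries several gold types the lowest canonical label wins
    (single-label training); evaluation handles multi-label gold separately.
    """
    gold: dict[tuple[str, str, str], RelationLabel] = {}
    for rel in relations:
        key = (rel.pmid, rel.arg1, rel.arg2)
        if key not in gold or rel.rtype < gold[key]:
            gold[key] = rel.rtype
    return [gold.get(p.pair_key, RelationLabel.NONE) for p in pairs]
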