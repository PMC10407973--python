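"""Readers and writers for DrugProt-style corpus files, CTD-style interaction
tables and prediction files.

All formats are UTF-8 tab-separated text:

* abstracts:   ``pmid<TAB>title<TAB>abstract``
* entities:    ``pmid<TAB>mention_id<TAB>etype<TAB>start<TAB>end<TAB>surface[<TAB>norm_id]``
* relations:   ``pmid<TAB>rtype<TAB>Arg1:<mention_id><TAB>Arg2:<mention_id>``
* predictions: header-led ``pmid<TAB>arg1<TAB>arg2<TAB>label[<TAB>score columns]``
* KB table:    header-driven; chemical id, gene id and supporting-PMIDs columns
  are required, everything else is carried verbatim.

A document's ``full_text`` is the title and the abstract joined by a single
tab character; entity offsets are 0-based, end-exclusive character offsets
into ``full_text``.  Every mention is validated on load: its span must slice
``full_text`` to exactly the recorded surface string.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

FULL_TEXT_SEPARATOR = "\t"


class RelationLabel(enum.IntEnum):
    """The 13 DrugProt relation types plus the NONE sentinel.

    Enum values define the canonical ordering used by every tie-break rule
    in the package (lower value wins).  NONE is never written to
    gold-relation files.
    """

    INHIBITOR = 0
    DIRECT_REGULATOR = 1
    SUBSTRATE = 2
    ACTIVATOR = 3
    INDIRECT_UPREGULATOR = 4
    INDIRECT_DOWNREGULATOR = 5
    ANTAGONIST = 6
    PRODUCT_OF = 7
    PART_OF = 8
    AGONIST = 9
    AGONIST_ACTIVATOR = 10
    SUBSTRATE_PRODUCT_OF = 11
    AGONIST_INHIBITOR = 12
    NONE = 13

    def to_string(self) -> str:
        return _LABEL_TO_STRING[self]

    @classmethod
    def from_string(cls, s: str) -> "RelationLabel":
        try:
            return _STRING_TO_LABEL[s]
        except KeyError:
            raise FormatError(f"unknown relation label: {s!r}") from None


_LABEL_TO_STRING = {
    RelationLabel.INHIBITOR: "INHIBITOR",
    RelationLabel.DIRECT_REGULATOR: "DIRECT-REGULATOR",
    RelationLabel.SUBSTRATE: "SUBSTRATE",
    RelationLabel.ACTIVATOR: "ACTIVATOR",
    RelationLabel.INDIRECT_UPREGULATOR: "INDIRECT-UPREGULATOR",
    RelationLabel.INDIRECT_DOWNREGULATOR: "INDIRECT-DOWNREGULATOR",
    RelationLabel.ANTAGONIST: "ANTAGONIST",
    RelationLabel.PRODUCT_OF: "PRODUCT-OF",
    RelationLabel.PART_OF: "PART-OF",
    RelationLabel.AGONIST: "AGONIST",
    RelationLabel.AGONIST_ACTIVATOR: "AGONIST-ACTIVATOR",
    RelationLabel.SUBSTRATE_PRODUCT_OF: "SUBSTRATE_PRODUCT-OF",
    RelationLabel.AGONIST_INHIBITOR: "AGONIST-INHIBITOR",
    RelationLabel.NONE: "NONE",
}
_STRING_TO_LABEL = {v: k for k, v in _LABEL_TO_STRING.items()}

#: The 13 positive (gold-writable) relation types, in canonical order.
POSITIVE_LABELS: tuple[RelationLabel, ...] = tuple(
    lab for lab in RelationLabel if lab is not RelationLabel.NONE
)
#: All 14 labels (13 types + NONE) in canonical order.
ALL_LABELS: tuple[RelationLabel, ...] = tuple(RelationLabel)


class FormatError(ValueError):
    """Malformed input file (bad column count, unknown label, bad header)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a corpus invariant."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity span, character-indexed into the document full text."""

    mention_id: str
    etype: str  # "CHEMICAL" or "GENE"
    start: int
    end: int
    surface: str
    norm_id: str | None = None

    def validate(self, full_text: str, pmid: str = "?") -> None:
        if not (0 <= self.start < self.end <= len(full_text)):
            raise ValidationError(
                f"mention {self.mention_id} in {pmid}: span "
                f"[{self.start}, {self.end}) outside document of length "
                f"{len(full_text)}"
            )
        sliced = full_text[self.start : self.end]
        if sliced != self.surface:
            raise ValidationError(
                f"mention {self.mention_id} in {pmid}: surface "
                f"{self.surface!r} != sliced text {sliced!r}"
            )
        if self.etype not in ("CHEMICAL", "GENE"):
            raise ValidationError(
                f"mention {self.mention_id} in {pmid}: unknown entity type "
                f"{self.etype!r}"
            )


@dataclass(frozen=True)
class GoldRelation:
    pmid: str
    rtype: RelationLabel
    arg1: str  # chemical mention_id
    arg2: str  # gene mention_id


@dataclass
class Document:
    """One abstract: title + abstract joined by a single tab into full_text."""

    pmid: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + FULL_TEXT_SEPARATOR + self.abstract

    def mention_by_id(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def validate(self) -> None:
        if not self.pmid:
            raise ValidationError("empty pmid")
        seen: set[str] = set()
        for m in self.mentions:
            if m.mention_id in seen:
                raise ValidationError(
                    f"duplicate mention id {m.mention_id} in {self.pmid}"
                )
            seen.add(m.mention_id)
            m.validate(self.full_text, self.pmid)


@dataclass
class DocumentSet:
    """An ordered, pmid-keyed collection of documents plus gold relations."""

    documents: dict[str, Document] = field(default_factory=dict)
    relations: list[GoldRelation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents.values())

    def __getitem__(self, pmid: str) -> Document:
        return self.documents[pmid]

    def n_mentions(self) -> int:
        return sum(len(d.mentions) for d in self)

    def validate(self) -> None:
        for doc in self:
            doc.validate()
        for rel in self.relations:
            doc = self.documents.get(rel.pmid)
            if doc is None:
                raise ValidationError(f"relation references unknown pmid {rel.pmid}")
            try:
                chem = doc.mention_by_id(rel.arg1)
                gene = doc.mention_by_id(rel.arg2)
            except KeyError as e:
                raise ValidationError(
                    f"relation in {rel.pmid} references unknown mention {e}"
                ) from None
            if chem.etype != "CHEMICAL" or gene.etype != "GENE":
                raise ValidationError(
                    f"relation in {rel.pmid} has mistyped arguments "
                    f"({chem.etype}, {gene.etype})"
                )


@dataclass(frozen=True)
class KBRecord:
    """One chemical-gene interaction row.  The action text is carried but
    never interpreted: the refinement step checks pair presence only."""

    chem_id: str
    gene_id: str
    pmids: frozenset[str] = frozenset()
    action: str = ""


@dataclass(frozen=True)
class PredictionRow:
    """One relation prediction for a (pmid, arg1, arg2) pair.

    ``scores`` is an optional per-label weight vector over ``ALL_LABELS``,
    in canonical label order.
    """

    pmid: str
    arg1: str
    arg2: str
    label: RelationLabel
    scores: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# DrugProt-style corpus files
# ---------------------------------------------------------------------------


def _split_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            yield lineno, line.split("\t")


def read_drugprot(
    abstracts_path: str | Path,
    entities_path: str | Path,
    relations_path: str | Path | None = None,
) -> DocumentSet:
    """Load a DrugProt-style corpus triplet into a validated DocumentSet.

    ``relations_path`` is optional; when omitted the document set carries no
    gold relations.  Every entity row must reference a PMID present in the
    abstracts file, and every span must slice the document full text to
    exactly the recorded surface form.
    """
    docset = DocumentSet()
    for lineno, cols in _split_rows(Path(abstracts_path)):
        if len(cols) != 3:
            raise FormatError(
                f"{abstracts_path}:{lineno}: expected 3 columns, got {len(cols)}"
            )
        pmid, title, abstract = cols
        if pmid in docset.documents:
            raise ValidationError(f"{abstracts_path}:{lineno}: duplicate pmid {pmid}")
        docset.documents[pmid] = Document(pmid=pmid, title=title, abstract=abstract)

    for lineno, cols in _split_rows(Path(entities_path)):
        if len(cols) not in (6, 7):
            raise FormatError(
                f"{entities_path}:{lineno}: expected 6 or 7 columns, got {len(cols)}"
            )
        pmid, mention_id, etype, start, end, surface = cols[:6]
        norm_id = cols[6] if len(cols) == 7 and cols[6] else None
        doc = docset.documents.get(pmid)
        if doc is None:
            raise ValidationError(
                f"{entities_path}:{lineno}: entity row references unknown "
                f"pmid {pmid}"
            )
        mention = EntityMention(
            mention_id=mention_id,
            etype=etype,
            start=int(start),
            end=int(end),
            surface=surface,
            norm_id=norm_id,
        )
        mention.validate(doc.full_text, pmid)
        doc.mentions.append(mention)

    # deterministic order regardless of input row order
    for doc in docset:
        doc.mentions.sort(key=lambda m: (m.start, m.end, m.mention_id))

    if relations_path is not None:
        for lineno, cols in _split_rows(Path(relations_path)):
            if len(cols) != 4:
                raise FormatError(
                    f"{relations_path}:{lineno}: expected 4 columns, got {len(cols)}"
                )
            pmid, rtype, arg1, arg2 = cols
            if not (arg1.startswith("Arg1:") and arg2.startswith("Arg2:")):
                raise FormatError(
                    f"{relations_path}:{lineno}: argument columns must be "
                    f"'Arg1:<id>' and 'Arg2:<id>'"
                )
            label = RelationLabel.from_string(rtype)
            if label is RelationLabel.NONE:
                raise ValidationError(
                    f"{relations_path}:{lineno}: NONE is not a gold relation type"
                )
            docset.relations.append(
                GoldRelation(pmid=pmid, rtype=label, arg1=arg1[5:], arg2=arg2[5:])
            )
        docset.relations.sort(
            key=lambda r: (r.pmid, r.arg1, r.arg2, int(r.rtype))
        )

    docset.validate()
    return docset


def write_drugprot(
    docset: DocumentSet,
    abstracts_path: str | Path,
    entities_path: str | Path,
    relations_path: str | Path | None = None,
) -> None:
    """Write a DocumentSet back out in the corpus triplet layout."""
    with open(abstracts_path, "w", encoding="utf-8") as fh:
        for doc in docset:
            fh.write(f"{doc.pmid}\t{doc.title}\t{doc.abstract}\n")
    with open(entities_path, "w", encoding="utf-8") as fh:
        for doc in docset:
            for m in doc.mentions:
                cols = [doc.pmid, m.mention_id, m.etype, str(m.start), str(m.end), m.surface]
                if m.norm_id is not None:
                    cols.append(m.norm_id)
                fh.write("\t".join(cols) + "\n")
    if relations_path is not None:
        with open(relations_path, "w", encoding="utf-8") as fh:
            for rel in docset.relations:
                fh.write(
                    f"{rel.pmid}\t{rel.rtype.to_string()}\t"
                    f"Arg1:{rel.arg1}\tArg2:{rel.arg2}\n"
                )


# ---------------------------------------------------------------------------
# CTD-style knowledge-base table
# ---------------------------------------------------------------------------

#: Default column names, matching the public CTD chem-gene interaction export.
DEFAULT_KB_COLUMNS: Mapping[str, str] = {
    "chem_id": "ChemicalID",
    "gene_id": "GeneID",
    "pmids": "PubMedIDs",
    "action": "InteractionActions",
}

PMID_DELIMITER = "|"


def read_kb(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[KBRecord]:
    """Read a CTD-style tab-separated chemical-gene interaction table.

    The file must carry a header naming at least the chemical-id, gene-id and
    supporting-PMIDs columns (names configurable through ``columns``).  Rows
    with an empty chemical or gene id are skipped with a logged count;
    duplicate pairs are preserved (de-duplication happens in the KB index).
    """
    colmap = dict(DEFAULT_KB_COLUMNS)
    if columns:
        colmap.update(columns)

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty KB file")
        header = header_line.split("\t")
        try:
            i_chem = header.index(colmap["chem_id"])
            i_gene = header.index(colmap["gene_id"])
            i_pmids = header.index(colmap["pmids"])
        except ValueError as e:
            raise FormatError(f"{path}: missing required KB column ({e})") from None
        i_action = header.index(colmap["action"]) if colmap["action"] in header else None

        records: list[KBRecord] = []
        n_skipped = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            chem_id = cols[i_chem].strip()
            gene_id = cols[i_gene].strip()
            if not chem_id or not gene_id:
                n_skipped += 1
                continue
            pmids_cell = cols[i_pmids].strip() if i_pmids < len(cols) else ""
            pmids = frozenset(
                p.strip() for p in pmids_cell.split(PMID_DELIMITER) if p.strip()
            )
            action = cols[i_action] if i_action is not None and i_action < len(cols) else ""
            records.append(
                KBRecord(chem_id=chem_id, gene_id=gene_id, pmids=pmids, action=action)
            )
    if n_skipped:
        logger.info("read_kb: skipped %d rows with empty chem/gene id", n_skipped)
    read_kb.last_skip_count = n_skipped  # type: ignore[attr-defined]
    return records


# ---------------------------------------------------------------------------
# Prediction files
# ---------------------------------------------------------------------------

SCORE_PRECISION = 9  # decimal digits kept in prediction files


def write_predictions(
    predictions: Sequence[PredictionRow], path: str | Path
) -> None:
    """Write predictions as header-led TSV; score columns are emitted only
    when every row carries scores."""
    with_scores = all(p.scores is not None for p in predictions) and len(predictions) > 0
    header = ["pmid", "arg1", "arg2", "label"]
    if with_scores:
        header += [f"score:{lab.to_string()}" for lab in ALL_LABELS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for p in predictions:
            cols = [p.pmid, p.arg1, p.arg2, p.label.to_string()]
            if with_scores:
                assert p.scores is not None and len(p.scores) == len(ALL_LABELS)
                cols += [f"{s:.{SCORE_PRECISION}f}" for s in p.scores]
            fh.write("\t".join(cols) + "\n")


def read_predictions(path: str | Path) -> list[PredictionRow]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header[:4] != ["pmid", "arg1", "arg2", "label"]:
            raise FormatError(f"{path}: unexpected prediction header {header[:4]}")
        with_scores = len(header) > 4
        rows: list[PredictionRow] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            label = RelationLabel.from_string(cols[3])
            scores = None
            if with_scores:
                scores = tuple(float(x) for x in cols[4:])
                if len(scores) != len(ALL_LABELS):
                    raise FormatError(
                        f"{path}:{lineno}: expected {len(ALL_LABELS)} scores, "
                        f"got {len(scores)}"
                    )
            rows.append(
                PredictionRow(pmid=cols[0], arg1=cols[1], arg2=cols[2], label=label, scores=scores)
            )
    return rows
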