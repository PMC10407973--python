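"""Seeded synthetic DrugProt-style corpora with a controllable knowledge
base, so every pipeline stage runs without any download.

Each document is an abstract of templated sentences.  A sentence either
expresses a planted chemical-gene relation through a type-specific trigger
phrase, or is a neutral co-occurrence (two entities, no relation).  The
label distribution defaults to the DrugProt training-set proportions, so
the generated corpora reproduce the heavy class skew of the real task,
including the three very rare types.  A CTD-style KB is emitted alongside:
a configurable fraction (``kb_coverage``) of the planted positive pairs is
listed, plus ``kb_noise`` pairs that never co-occur in the text.

What the generator does NOT emulate: real biomedical syntax, entity-name
ambiguity, cross-sentence relations, or KB/corpus vocabulary mismatch
beyond pair-level noise.  Results on these fixtures demonstrate pipeline
correctness and directional behaviour, not real-corpus performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    Document,
    DocumentSet,
    EntityMention,
    GoldRelation,
    KBRecord,
    POSITIVE_LABELS,
    RelationLabel,
    write_drugprot,
)

# DrugProt training-set relation counts (public corpus statistics); the
# default label distribution is these counts normalized.
DRUGPROT_TRAIN_COUNTS: dict[RelationLabel, int] = {
    RelationLabel.INHIBITOR: 5392,
    RelationLabel.DIRECT_REGULATOR: 2250,
    RelationLabel.SUBSTRATE: 2003,
    RelationLabel.ACTIVATOR: 1429,
    RelationLabel.INDIRECT_UPREGULATOR: 1379,
    RelationLabel.INDIRECT_DOWNREGULATOR: 1330,
    RelationLabel.ANTAGONIST: 972,
    RelationLabel.PRODUCT_OF: 921,
    RelationLabel.PART_OF: 886,
    RelationLabel.AGONIST: 659,
    RelationLabel.AGONIST_ACTIVATOR: 29,
    RelationLabel.SUBSTRATE_PRODUCT_OF: 25,
    RelationLabel.AGONIST_INHIBITOR: 13,
}


def default_label_distribution() -> dict[RelationLabel, float]:
    total = sum(DRUGPROT_TRAIN_COUNTS.values())
    return {k: v / total for k, v in DRUGPROT_TRAIN_COUNTS.items()}


#: Per-type trigger templates.  Triggers are unambiguous by construction so
#: a desk-scale linear classifier can learn them; ambiguity enters only
#: through neutral co-occurrence sentences and distractor mentions.
TYPE_TEMPLATES: dict[RelationLabel, list[str]] = {
    RelationLabel.INHIBITOR: [
        "{chem} potently inhibited {gene} activity in vitro.",
        "{chem} was a slow-binding inhibitor of {gene}.",
        "Enzymatic assays showed that {chem} inhibited {gene}.",
    ],
    RelationLabel.DIRECT_REGULATOR: [
        "{chem} bound directly to {gene} and modulated its conformation.",
        "{chem} directly regulated {gene} through physical binding.",
        "Binding studies confirmed that {chem} directly regulated {gene}.",
    ],
    RelationLabel.SUBSTRATE: [
        "{chem} was efficiently metabolized by {gene}.",
        "{chem} served as a substrate for {gene}.",
        "Kinetic analyses identified {chem} as a substrate of {gene}.",
    ],
    RelationLabel.ACTIVATOR: [
        "{chem} markedly activated {gene} in dose-response experiments.",
        "{chem} acted as an activator of {gene} catalysis.",
        "Reporter assays showed that {chem} activated {gene}.",
    ],
    RelationLabel.INDIRECT_UPREGULATOR: [
        "{chem} treatment upregulated {gene} expression.",
        "Exposure to {chem} increased transcription of {gene}.",
        "{chem} indirectly upregulated {gene} via downstream signalling.",
    ],
    RelationLabel.INDIRECT_DOWNREGULATOR: [
        "{chem} treatment downregulated {gene} expression.",
        "Exposure to {chem} suppressed transcription of {gene}.",
        "{chem} indirectly downregulated {gene} via downstream signalling.",
    ],
    RelationLabel.ANTAGONIST: [
        "{chem} antagonized {gene} with nanomolar affinity.",
        "{chem} acted as a selective antagonist of {gene}.",
        "Radioligand assays showed that {chem} antagonized {gene}.",
    ],
    RelationLabel.PRODUCT_OF: [
        "{chem} was generated as a product of {gene} catalysis.",
        "{chem} accumulated as the main reaction product of {gene}.",
        "Metabolite profiling showed {chem} to be a product of {gene}.",
    ],
    RelationLabel.PART_OF: [
        "{chem} was a structural component of the {gene} complex.",
        "{chem} formed part of the {gene} holoenzyme.",
        "Structural analysis placed {chem} as part of {gene}.",
    ],
    RelationLabel.AGONIST: [
        "{chem} behaved as a full agonist of {gene}.",
        "{chem} was a potent agonist at {gene} receptors.",
        "Functional assays classified {chem} as an agonist of {gene}.",
    ],
    RelationLabel.AGONIST_ACTIVATOR: [
        "{chem} was an agonist that further activated {gene} signalling.",
        "As an agonist, {chem} additionally activated {gene} currents.",
        "{chem} acted as an agonist-activator of {gene}.",
    ],
    RelationLabel.SUBSTRATE_PRODUCT_OF: [
        "{chem} was both a substrate and a product of {gene}.",
        "{chem} cycled as substrate and product of {gene}.",
        "Flux experiments showed {chem} as substrate and product of {gene}.",
    ],
    RelationLabel.AGONIST_INHIBITOR: [
        "{chem} was an agonist that paradoxically inhibited {gene}.",
        "As an agonist, {chem} nevertheless inhibited {gene} turnover.",
        "{chem} acted as an agonist-inhibitor of {gene}.",
    ],
}

NEGATIVE_TEMPLATES = [
    "The study quantified {chem} concentrations and {gene} transcript abundance.",
    "Samples were screened for {chem} content and {gene} expression.",
    "{chem} and {gene} were included in the multiplexed assay panel.",
    "Baseline measurements covered {chem} exposure and {gene} status.",
]

DISTRACTOR_CLAUSES = [
    ", while {distractor} remained unchanged.",
    ", whereas {distractor} levels were stable.",
    ", and {distractor} was unaffected.",
]

_CHEM_PREFIX = ["Alvo", "Beta", "Cari", "Dexo", "Enzo", "Fluri", "Galo", "Hexi", "Ibro", "Jatro"]
_CHEM_CORE = ["ci", "da", "lo", "mi", "na", "pra", "ri", "ta"]
_CHEM_SUFFIX = ["dib", "mab", "nib", "prazole", "statin", "cillin", "micin", "olol"]


def chem_surface(i: int) -> str:
    p, c, s = len(_CHEM_PREFIX), len(_CHEM_CORE), len(_CHEM_SUFFIX)
    if i >= p * c * s:
        raise ValueError(f"chemical lexicon capacity {p * c * s} exceeded")
    return _CHEM_PREFIX[i % p] + _CHEM_CORE[(i // p) % c] + _CHEM_SUFFIX[(i // (p * c)) % s]


def gene_surface(i: int) -> str:
    if i >= 26 * 26 * 26 * 9:
        raise ValueError("gene lexicon capacity exceeded")
    a, b, c = (i // 676) % 26, (i // 26) % 26, i % 26
    return f"{chr(65 + a)}{chr(65 + b)}{chr(65 + c)}{1 + (i % 9)}"


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings.  Defaults are the standard study conditions used
    throughout the test suite and the reproduction script."""

    n_docs: int = 300
    sentences_per_doc: tuple[int, int] = (3, 8)  # inclusive range
    chem_lexicon_size: int = 120
    gene_lexicon_size: int = 120
    label_distribution: tuple[tuple[RelationLabel, float], ...] = tuple(
        default_label_distribution().items()
    )
    p_negative_cooccurrence: float = 0.3
    p_distractor: float = 0.25
    kb_coverage: float = 0.9
    kb_noise: int = 50
    seed: int = 0

    def __post_init__(self):
        probs = dict(self.label_distribution)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("label_distribution must sum to 1")
        if set(probs) != set(POSITIVE_LABELS):
            raise ValueError("label_distribution must cover the 13 positive types")
        if not (0.0 <= self.kb_coverage <= 1.0):
            raise ValueError("kb_coverage must lie in [0, 1]")
        if self.kb_noise < 0:
            raise ValueError("kb_noise must be >= 0")


@dataclass(frozen=True)
class PlantedRelation:
    """Ground-truth manifest entry for one planted relation occurrence."""

    pmid: str
    chem_mention_id: str
    gene_mention_id: str
    chem_norm_id: str
    gene_norm_id: str
    label: RelationLabel


@dataclass
class FixtureBundle:
    """A generated corpus: documents + gold relations (formats_io dialect),
    a CTD-style KB, and the ground-truth manifest of planted relations."""

    config: FixtureConfig
    docset: DocumentSet
    kb_records: list[KBRecord]
    manifest: list[PlantedRelation]
    covered_pairs: set[tuple[str, str]] = field(default_factory=set)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write abstracts/entities/relations/KB files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "abstracts": out / "abstracts.tsv",
            "entities": out / "entities.tsv",
            "relations": out / "relations.tsv",
            "kb": out / "kb.tsv",
        }
        write_drugprot(
            self.docset, paths["abstracts"], paths["entities"], paths["relations"]
        )
        with open(paths["kb"], "w", encoding="utf-8") as fh:
            fh.write("ChemicalID\tGeneID\tPubMedIDs\tInteractionActions\n")
            for rec in self.kb_records:
                fh.write(
                    f"{rec.chem_id}\t{rec.gene_id}\t"
                    f"{'|'.join(sorted(rec.pmids))}\t{rec.action}\n"
                )
        return paths


def _realize(template: str, chem: str, gene: str, distractor: str | None) -> tuple[str, tuple[int, int], tuple[int, int], tuple[int, int] | None]:
    """Fill a template; returns the text and the character spans of the
    chemical, gene and optional distractor-gene surfaces."""
    text = template
    spans: dict[str, tuple[int, int]] = {}
    for key, value in (("{chem}", chem), ("{gene}", gene), ("{distractor}", distractor or "")):
        idx = text.find(key)
        if idx < 0:
            continue
        text = text[:idx] + value + text[idx + len(key):]
        spans[key] = (idx, idx + len(value))
        # shift any span recorded before this one if it sits after idx
        for k2, (s2, e2) in list(spans.items()):
            if k2 != key and s2 > idx:
                delta = len(value) - len(key)
                spans[k2] = (s2 + delta, e2 + delta)
    return (
        text,
        spans["{chem}"],
        spans["{gene}"],
        spans.get("{distractor}"),
    )


def generate(config: FixtureConfig = FixtureConfig()) -> FixtureBundle:
    """Generate a corpus bundle; byte-identical given the same config."""
    rng = np.random.default_rng(config.seed)
    if config.chem_lexicon_size < 2 or config.gene_lexicon_size < 2:
        raise ValueError("lexicons too small for distinct candidate pairs")

    chems = [(chem_surface(i), f"MESH:C{i:05d}") for i in range(config.chem_lexicon_size)]
    genes = [(gene_surface(i), f"NCBIGene:{1000 + i}") for i in range(config.gene_lexicon_size)]
    labels, probs = zip(*config.label_distribution)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()

    docset = DocumentSet()
    manifest: list[PlantedRelation] = []
    cooccurring: set[tuple[str, str]] = set()  # all pairs co-occurring in any sentence

    for d in range(config.n_docs):
        pmid = str(10000 + d)
        title = f"Chemical-gene interaction screening report {pmid}."
        lo, hi = config.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        sentences: list[str] = []
        mentions: list[EntityMention] = []
        relations: list[GoldRelation] = []
        abs_pos = 0  # position within the abstract
        mid_counter = 0

        for _s in range(n_sent):
            ci = int(rng.integers(len(chems)))
            gi = int(rng.integers(len(genes)))
            chem_sf, chem_id = chems[ci]
            gene_sf, gene_id = genes[gi]
            is_negative = rng.random() < config.p_negative_cooccurrence
            if is_negative:
                template = NEGATIVE_TEMPLATES[int(rng.integers(len(NEGATIVE_TEMPLATES)))]
                label = None
            else:
                label = labels[int(rng.choice(len(labels), p=probs))]
                variants = TYPE_TEMPLATES[label]
                template = variants[int(rng.integers(len(variants)))]

            distractor = None
            if rng.random() < config.p_distractor:
                di = int(rng.integers(len(genes)))
                if di != gi:
                    distractor = genes[di]
                    clause = DISTRACTOR_CLAUSES[int(rng.integers(len(DISTRACTOR_CLAUSES)))]
                    template = template[:-1] + clause  # replace final period

            text, chem_span, gene_span, dspan = _realize(
                template, chem_sf, gene_sf, distractor[0] if distractor else None
            )

            new_mentions = [("CHEMICAL", chem_sf, chem_id, chem_span)]
            new_mentions.append(("GENE", gene_sf, gene_id, gene_span))
            if distractor is not None and dspan is not None:
                new_mentions.append(("GENE", distractor[0], distractor[1], dspan))

            ids: list[str] = []
            for etype, sf, nid, (s, e) in new_mentions:
                mid_counter += 1
                mid = f"T{mid_counter}"
                ids.append(mid)
                mentions.append(
                    EntityMention(
                        mention_id=mid,
                        etype=etype,
                        start=abs_pos + s,  # abstract-local; shifted below
                        end=abs_pos + e,
                        surface=sf,
                        norm_id=nid,
                    )
                )
            cooccurring.add((chem_id, gene_id))
            if distractor is not None and dspan is not None:
                cooccurring.add((chem_id, distractor[1]))
            if label is not None:
                relations.append(
                    GoldRelation(pmid=pmid, rtype=label, arg1=ids[0], arg2=ids[1])
                )
                manifest.append(
                    PlantedRelation(
                        pmid=pmid,
                        chem_mention_id=ids[0],
                        gene_mention_id=ids[1],
                        chem_norm_id=chem_id,
                        gene_norm_id=gene_id,
                        label=label,
                    )
                )
            sentences.append(text)
            abs_pos += len(text) + 1  # single joining space

        abstract = " ".join(sentences)
        offset = len(title) + 1  # title + tab separator
        doc = Document(
            pmid=pmid,
            title=title,
            abstract=abstract,
            mentions=[
                EntityMention(
                    mention_id=m.mention_id,
                    etype=m.etype,
                    start=m.start + offset,
                    end=m.end + offset,
                    surface=m.surface,
                    norm_id=m.norm_id,
                )
                for m in mentions
            ],
        )
        docset.documents[pmid] = doc
        docset.relations.extend(relations)

    docset.validate()

    # ---- knowledge base ----
    planted_pairs = sorted(
        {(p.chem_norm_id, p.gene_norm_id) for p in manifest}
    )
    pair_docs: dict[tuple[str, str], set[str]] = {}
    for p in manifest:
        pair_docs.setdefault((p.chem_norm_id, p.gene_norm_id), set()).add(p.pmid)

    covered: set[tuple[str, str]] = set()
    kb_records: list[KBRecord] = []
    for pair in planted_pairs:
        if rng.random() < config.kb_coverage:
            covered.add(pair)
            kb_records.append(
                KBRecord(
                    chem_id=pair[0],
                    gene_id=pair[1],
                    pmids=frozenset(pair_docs[pair]),
                    action="interaction",
                )
            )

    all_pairs = [
        (c[1], g[1]) for c in chems for g in genes
    ]
    unexpressed = [p for p in all_pairs if p not in cooccurring]
    if config.kb_noise > len(unexpressed):
        raise ValueError(
            f"lexicons too small: cannot draw {config.kb_noise} KB noise pairs "
            f"from {len(unexpressed)} unexpressed pairs"
        )
    if config.kb_noise:
        noise_idx = rng.choice(len(unexpressed), size=config.kb_noise, replace=False)
        for j, i in enumerate(sorted(int(x) for x in noise_idx)):
            c_id, g_id = unexpressed[i]
            kb_records.append(
                KBRecord(
                    chem_id=c_id,
                    gene_id=g_id,
                    pmids=frozenset({str(7000000 + j)}),
                    action="interaction",
                )
            )

    return FixtureBundle(
        config=config,
        docset=docset,
        kb_records=kb_records,
        manifest=manifest,
        covered_pairs=covered,
    )


def planted_truth(bundle: FixtureBundle) -> list[tuple[str, str, str, RelationLabel]]:
    """Exact gold relation tuples of a bundle generated here."""
    if not isinstance(bundle, FixtureBundle) or bundle.manifest is None:
        raise ValueError("planted_truth requires a bundle generated by this module")
    return [
        (p.pmid, p.chem_mention_id, p.gene_mention_id, p.label)
        for p in bundle.manifest
    ]
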