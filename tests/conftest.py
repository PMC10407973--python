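import pytest

from kbrelex import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def small_bundle():
    """A small generated corpus shared by read-only tests."""
    return sf.generate(sf.FixtureConfig(n_docs=40, kb_noise=20, seed=7))


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write(out)
    return paths


@pytest.fixture
def toy_corpus(tmp_path):
    """Hand-written corpus triplet: 2 abstracts, 5 entities, 2 relations."""
    title1 = "Kinase assay report."
    abs1 = "Aspirin potently inhibited COX2 activity. MTX bound DHFR tightly."
    title2 = "Receptor screening."
    abs2 = "Caffeine antagonized ADORA2A in cells."

    abstracts = tmp_path / "abstracts.tsv"
    abstracts.write_text(
        f"101\t{title1}\t{abs1}\n102\t{title2}\t{abs2}\n", encoding="utf-8"
    )

    def span(title, abstract, needle):
        i = abstract.index(needle)
        off = len(title) + 1
        return off + i, off + i + len(needle)

    rows = []
    for pmid, title, abstract, mid, etype, needle, nid in [
        ("101", title1, abs1, "T1", "CHEMICAL", "Aspirin", "MESH:D001241"),
        ("101", title1, abs1, "T2", "GENE", "COX2", "NCBIGene:5743"),
        ("101", title1, abs1, "T3", "CHEMICAL", "MTX", "MESH:D008727"),
        ("101", title1, abs1, "T4", "GENE", "DHFR", "NCBIGene:1719"),
        ("102", title2, abs2, "T1", "CHEMICAL", "Caffeine", "MESH:D002110"),
    ]:
        s, e = span(title, abstract, needle)
        rows.append(f"{pmid}\t{mid}\t{etype}\t{s}\t{e}\t{needle}\t{nid}")
    entities = tmp_path / "entities.tsv"
    entities.write_text("\n".join(rows) + "\n", encoding="utf-8")

    relations = tmp_path / "relations.tsv"
    relations.write_text(
        "101\tINHIBITOR\tArg1:T1\tArg2:T2\n"
        "101\tDIRECT-REGULATOR\tArg1:T3\tArg2:T4\n",
        encoding="utf-8",
    )
    return {"abstracts": abstracts, "entities": entities, "relations": relations}
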