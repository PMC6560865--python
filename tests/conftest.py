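import pytest

from structforge.homology import SequenceBackend
from structforge.splits import SplitConfig, extract_validation_sets
from structforge.synthetic import FamilySpec, generate_families

#: Corpus conditions for the ladder-scale suite: enough well-separated
#: families that every one of the seven thresholds still has more than 32
#: candidate clusters after the earlier levels consumed theirs.
LADDER_SPEC = FamilySpec(
    n_families=260,
    members_per_family=(2, 4),
    within_identity=(95.0, 99.0),
    length=(200, 250),
    seed=7,
)


@pytest.fixture(scope="session")
def small_corpus():
    """12 independent families, 2-4 members each."""
    return generate_families(
        FamilySpec(n_families=12, members_per_family=(2, 4), length=(200, 240), seed=11)
    )


@pytest.fixture(scope="session")
def small_graph(small_corpus):
    return SequenceBackend(small_corpus.sequences).build_graph()


@pytest.fixture(scope="session")
def small_split(small_corpus, small_graph):
    cfg = SplitConfig(clusters_per_level=1, seed=5)
    return extract_validation_sets(small_corpus.entries, small_graph, cfg)


@pytest.fixture(scope="session")
def ladder_corpus():
    return generate_families(LADDER_SPEC)


@pytest.fixture(scope="session")
def ladder_dir(tmp_path_factory, ladder_corpus):
    """The ladder corpus written in on-disk form for CLI-level tests."""
    d = tmp_path_factory.mktemp("ladder")
    ladder_corpus.write(d)
    return d


@pytest.fixture(scope="session")
def ladder_split_dir(ladder_dir):
    """Output directory of a full `forge split` run over the ladder corpus."""
    from click.testing import CliRunner

    from structforge.cli import main

    out = ladder_dir / "split"
    runner = CliRunner()
    result = runner.invoke(
        main,
        [
            "split",
            "--entries", str(ladder_dir / "structures.tsv"),
            "--seed", "2020",
            "--out", str(out),
        ],
        catch_exceptions=False,
    )
    assert result.exit_code == 0, result.output
    return out
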