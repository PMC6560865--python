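import datetime as dt
import io
import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structforge.homology import IdentityGraph, PairScore, SequenceBackend, cluster
from structforge.splits import (
    SplitConfig,
    extract_validation_sets,
    make_thinnings,
    read_split_manifest,
    select_exemplar,
    write_split_manifest,
)
from structforge.structures import quality_score
from structforge.synthetic import FamilySpec, generate_contained_domain, generate_families

from _utils import make_entry


def _graph(pairs, nodes):
    g = IdentityGraph(nodes=nodes)
    for a, b, ident, cov_a, cov_b in pairs:
        g.add_edge(PairScore(a, b, ident, cov_a, cov_b, 1e-9))
    return g


class TestSplitConfig:
    def test_defaults_reflect_the_standard_ladder(self):
        cfg = SplitConfig()
        assert cfg.thresholds == (10, 20, 30, 40, 50, 70, 90)
        assert cfg.clusters_per_level == 32
        assert cfg.max_cluster_size == 100
        assert cfg.thinning_levels == (30, 50, 70, 90, 95, 100)
        assert cfg.thinning_coverage == 0.80

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            SplitConfig(thresholds=(10, 10, 30))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SplitConfig(seed=9, clusters_per_level=4)
        path = tmp_path / "cfg.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SplitConfig.from_yaml(path) == cfg


class TestSelectExemplar:
    def test_singleton_cluster(self):
        e = make_entry("solo", "ACDEF")
        g = IdentityGraph(nodes=["solo"])
        assert select_exemplar(["solo"], {"solo": e}, g) == "solo"

    def test_better_quality_member_of_tight_cluster_beats_bait(self):
        # bait b: quality 1/2.5 - 0.25 = 0.15; m: 1/1.5 - 0.20 = 0.4667
        entries = {
            "b": make_entry("b", "A" * 50, resolution=2.5, r_value=0.25),
            "m": make_entry("m", "A" * 50, resolution=1.5, r_value=0.20),
            "c": make_entry("c", "A" * 50, resolution=1.0, r_value=0.10),
        }
        g = _graph(
            [
                ("b", "m", 96.0, 0.95, 0.95),
                ("b", "c", 93.0, 1.0, 1.0),  # medoid is b; c is outside the tight set
            ],
            entries,
        )
        assert quality_score(1.5, 0.20) == pytest.approx(0.4667, abs=1e-4)
        assert select_exemplar(entries, entries, g) == "m"

    def test_member_below_tight_coverage_excluded(self):
        entries = {
            "b": make_entry("b", "A" * 50, resolution=2.5, r_value=0.25),
            "m": make_entry("m", "A" * 50, resolution=1.5, r_value=0.20),
        }
        g = _graph([("b", "m", 96.0, 0.85, 1.0)], entries)  # covers only 85% of bait
        assert select_exemplar(entries, entries, g) == "b"

    def test_quality_tie_newer_date_wins(self):
        entries = {
            "b": make_entry("b", "A" * 50, date=dt.date(2004, 1, 1)),
            "m": make_entry("m", "A" * 50, date=dt.date(2005, 1, 1)),
        }
        g = _graph([("b", "m", 96.0, 0.95, 0.95)], entries)
        assert select_exemplar(entries, entries, g) == "m"

    def test_quality_and_date_tie_longer_wins(self):
        entries = {
            "b": make_entry("b", "A" * 50),
            "m": make_entry("m", "A" * 60),
        }
        g = _graph([("b", "m", 96.0, 0.95, 0.95)], entries)
        assert select_exemplar(entries, entries, g) == "m"

    def test_missing_quality_ranks_below_any_quality(self):
        entries = {
            "b": make_entry("b", "A" * 50, resolution=None, r_value=None),
            "m": make_entry("m", "A" * 50, resolution=3.9, r_value=0.35),
        }
        g = _graph([("b", "m", 96.0, 0.95, 0.95)], entries)
        assert select_exemplar(entries, entries, g) == "m"

    @given(seed=st.integers(0, 10 ** 6))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_exhaustive_search_on_small_clusters(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 8)
        members = [f"m{i}" for i in range(n)]
        entries = {
            m: make_entry(
                m,
                "A" * rng.randint(20, 60),
                date=dt.date(2000 + rng.randint(0, 9), 1, 1),
                resolution=rng.choice([None, round(rng.uniform(1, 4), 2)]),
                r_value=round(rng.uniform(0.15, 0.35), 3),
            )
            for m in members
        }
        pairs = []
        for a, b in itertools.combinations(members, 2):
            if rng.random() < 0.7:
                pairs.append(
                    (a, b, rng.uniform(80, 100), rng.uniform(0.7, 1.0), rng.uniform(0.7, 1.0))
                )
        g = _graph(pairs, members)

        # independent enumeration of the documented selection procedure
        def total_identity(m):
            return sum(g.identity(m, o) for o in members if o != m)

        bait = min(members, key=lambda m: (-total_identity(m), m))
        cands = [bait]
        for m in members:
            e = g.edge(bait, m)
            if m != bait and e and e.identity >= 95 and e.coverage_of(bait) >= 0.90:
                cands.append(m)
        date0 = dt.date.min

        def rank(m):
            e = entries[m]
            q = quality_score(e.resolution, e.r_value)
            return (-q, -(e.release_date or date0).toordinal(), -e.length, m)

        expected = min(cands, key=rank)
        assert select_exemplar(members, entries, g) == expected


class TestExtractValidationSets:
    def test_well_separated_families_fill_every_level(self, small_corpus, small_graph, small_split):
        res = small_split
        assert sorted(res.validation) == [10, 20, 30, 40, 50, 70, 90]
        for t, ids in res.validation.items():
            assert len(ids) == 1  # clusters_per_level=1 in the fixture

    def test_partition_invariant(self, small_corpus, small_split):
        res = small_split
        groups = [set(res.training_pool), res.all_validation_ids()]
        groups += [set(v) for v in res.removed.values()]
        union = set().union(*groups)
        assert union == set(small_corpus.entries)
        assert sum(len(g) for g in groups) == len(union)

    def test_validation_sets_pairwise_disjoint(self, small_split):
        ids = [set(v) for v in small_split.validation.values()]
        for a, b in itertools.combinations(ids, 2):
            assert not (a & b)

    def test_single_entry_input(self):
        e = make_entry("only", "ACDEFGHIKL")
        g = IdentityGraph(nodes=["only"])
        res = extract_validation_sets({"only": e}, g, SplitConfig(seed=1))
        assert res.validation[10.0] == ["only"]
        assert all(res.validation[t] == [] for t in res.validation if t != 10.0)
        assert res.training_pool == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_validation_sets({}, IdentityGraph(), SplitConfig())

    def test_same_seed_reproduces_result_exactly(self, small_corpus, small_graph):
        cfg = SplitConfig(clusters_per_level=2, seed=13)
        r1 = extract_validation_sets(small_corpus.entries, small_graph, cfg)
        r2 = extract_validation_sets(small_corpus.entries, small_graph, cfg)
        assert r1.validation == r2.validation
        assert r1.training_pool == r2.training_pool
        assert r1.removed == r2.removed
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_split_manifest(r1, buf1)
        write_split_manifest(r2, buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_different_seed_draws_different_clusters(self, small_corpus, small_graph):
        draws = set()
        for seed in range(4):
            cfg = SplitConfig(clusters_per_level=1, seed=seed)
            res = extract_validation_sets(small_corpus.entries, small_graph, cfg)
            draws.add(tuple(sorted(res.all_validation_ids())))
        assert len(draws) > 1

    def test_oversized_clusters_are_not_candidates(self):
        # one giant cluster of 5 members with max_cluster_size 4 plus two
        # singletons: the giant cluster must never be drawn
        members = [f"g{i}" for i in range(5)]
        entries = {m: make_entry(m, "A" * 30) for m in members + ["s1", "s2"]}
        pairs = [(members[i], members[i + 1], 99.0, 1.0, 1.0) for i in range(4)]
        g = _graph(pairs, entries)
        cfg = SplitConfig(
            thresholds=(50.0,), clusters_per_level=10, max_cluster_size=4, seed=0
        )
        res = extract_validation_sets(entries, g, cfg)
        assert set(res.validation[50.0]) == {"s1", "s2"}
        assert set(res.training_pool) == set(members)

    def test_removed_members_bounded_by_draw_budget(self, small_split):
        cfg = SplitConfig()
        bound = cfg.clusters_per_level * cfg.max_cluster_size
        assert bound == 3200
        for t, ids in small_split.removed.items():
            assert len(ids) <= bound

    def test_manifest_round_trip(self, small_split, tmp_path):
        path = tmp_path / "manifest.tsv"
        write_split_manifest(small_split, path)
        validation, training = read_split_manifest(path)
        assert validation == small_split.validation
        assert training == small_split.training_pool


class TestThinnings:
    def test_mutually_unrelated_pool_is_never_thinned(self):
        corpus = generate_families(
            FamilySpec(n_families=6, members_per_family=(1, 1), length=(150, 180), seed=21)
        )
        g = SequenceBackend(corpus.sequences).build_graph()
        cfg = SplitConfig()
        th = make_thinnings(sorted(corpus.entries), corpus.entries, g, cfg)
        for level, ids in th.items():
            assert sorted(ids) == sorted(corpus.entries)

    def test_identical_sequences_collapse_at_100(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        entries = {
            "a": make_entry("a", seq, resolution=2.0),
            "b": make_entry("b", seq, resolution=1.0),  # better quality
            "c": make_entry("c", "".join(reversed(seq))),
        }
        g = SequenceBackend({i: e.sequence for i, e in entries.items()}).build_graph()
        th = make_thinnings(sorted(entries), entries, g, SplitConfig())
        assert set(th[100.0]) == {"b", "c"}  # the duplicate pair keeps its best member

    def test_contained_domain_never_merges_below_100(self):
        long_e, short_e = generate_contained_domain(400, (101, 300), seed=2)  # coverage 0.5
        entries = {long_e.id: long_e, short_e.id: short_e}
        g = SequenceBackend({i: e.sequence for i, e in entries.items()}).build_graph()
        th = make_thinnings(sorted(entries), entries, g, SplitConfig())
        for level, ids in th.items():
            assert len(ids) == 2, f"level {level} merged the domain with its container"

    def test_coverage_boundary_at_80_percent(self):
        # identical pair; coverage of the long one exactly 0.8 merges,
        # just below 0.8 does not
        entries = {
            "long": make_entry("long", "A" * 100),
            "short": make_entry("short", "A" * 80),
        }
        g80 = _graph([("long", "short", 100.0, 0.80, 1.0)], entries)
        g79 = _graph([("long", "short", 100.0, 0.79, 1.0)], entries)
        cfg = SplitConfig()
        assert len(make_thinnings(sorted(entries), entries, g80, cfg)[30.0]) == 1
        assert len(make_thinnings(sorted(entries), entries, g79, cfg)[30.0]) == 2

    def test_thinning_sizes_are_monotone(self, small_corpus, small_graph, small_split):
        th = make_thinnings(
            small_split.training_pool, small_corpus.entries, small_graph, SplitConfig()
        )
        sizes = [len(th[level]) for level in sorted(th)]
        assert sizes == sorted(sizes)

    def test_empty_pool_rejected(self, small_corpus, small_graph):
        with pytest.raises(ValueError):
            make_thinnings([], small_corpus.entries, small_graph, SplitConfig())
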