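"""Validation-ladder extraction, exemplar selection, and training thinnings.

The split procedure partitions a pool of entries into one training set and
seven non-overlapping validation sets at increasing sequence-identity
thresholds (10, 20, 30, 40, 50, 70, 90% by default).  At each threshold the
remaining entries are clustered by transitive closure (no coverage
requirement, the conservative convention against information leakage);
clusters larger than 100 members are not considered, 32 of the candidate
clusters are drawn at random, one exemplar is kept from each drawn cluster,
and the remaining members of those clusters are removed outright.  Whatever
survives all seven levels is the training pool.

Exemplar selection avoids cluster boundaries: the medoid is used as bait to
form a tight cluster of entries at least 95% identical to it covering at
least 90% of its length; from the intersection of tight cluster and original
cluster the entry with the best structure quality (1/resolution - R-value)
is kept, with newer release date, then greater length, then smallest id as
successive tie-breaks.

Thinnings are redundancy-reduced subsets of the training pool at 30, 50, 70,
90, 95 and 100% identity.  Below 100% they cluster plain sequences with an
80% mutual-coverage requirement — which keeps single domains from being
grouped with multi-domain proteins containing them — and keep one exemplar
per cluster; at 100% every set of exactly identical sequences forms a
cluster.
"""

from __future__ import annotations

import datetime as _dt
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import yaml

from structforge.homology import IdentityGraph, cluster, medoid
from structforge.structures import StructureEntry

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (10.0, 20.0, 30.0, 40.0, 50.0, 70.0, 90.0)
DEFAULT_THINNING_LEVELS = (30.0, 50.0, 70.0, 90.0, 95.0, 100.0)


@dataclass
class SplitConfig:
    """Parameters of the split and thinning procedure."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    clusters_per_level: int = 32
    max_cluster_size: int = 100
    seed: int = 0
    exemplar_tight_identity: float = 95.0
    exemplar_tight_coverage: float = 0.90
    thinning_levels: tuple[float, ...] = DEFAULT_THINNING_LEVELS
    thinning_coverage: float = 0.80

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        self.thinning_levels = tuple(float(t) for t in self.thinning_levels)
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        for t in self.thresholds + self.thinning_levels + (
            self.exemplar_tight_identity,
        ):
            if not 0 < t <= 100:
                raise ValueError(f"percent value out of (0, 100]: {t}")
        if self.clusters_per_level <= 0 or self.max_cluster_size <= 0:
            raise ValueError("counts must be positive")
        for c in (self.exemplar_tight_coverage, self.thinning_coverage):
            if not 0 < c <= 1:
                raise ValueError(f"coverage fraction out of (0, 1]: {c}")

    @classmethod
    def from_yaml(cls, source: Union[str, Path, TextIO]) -> "SplitConfig":
        own = not hasattr(source, "read")
        fh = open(source) if own else source
        try:
            data = yaml.safe_load(fh) or {}
        finally:
            if own:
                fh.close()
        for key in ("thresholds", "thinning_levels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["thinning_levels"] = list(self.thinning_levels)
        return d


@dataclass
class SplitResult:
    """Outcome of the validation-ladder extraction.

    ``validation`` maps each threshold to its exemplar ids; ``removed`` maps
    each threshold to the non-exemplar members of the drawn clusters;
    ``training_pool`` is everything never drawn into a validation cluster.
    The three parts partition the input id set.
    """

    validation: dict[float, list[str]]
    training_pool: list[str]
    removed: dict[float, list[str]]
    provenance: dict = field(default_factory=dict)

    def all_validation_ids(self) -> set[str]:
        return {i for ids in self.validation.values() for i in ids}


def _rank_key(entry: StructureEntry):
    # maximize quality, then newer date, then longer; date absent ranks oldest
    date = entry.release_date or _dt.date.min
    return (entry.quality, date.toordinal(), entry.length)


def select_exemplar(
    cluster_members: Iterable[str],
    entries: Mapping[str, StructureEntry],
    graph: IdentityGraph,
    tight_identity: float = 95.0,
    tight_coverage: float = 0.90,
    universe: Iterable[str] | None = None,
) -> str:
    """Pick the cluster's representative entry.

    The medoid serves as bait; candidates are cluster members that are at
    least ``tight_identity`` percent identical to the bait and whose
    alignment covers at least ``tight_coverage`` of the bait's length
    (coverage is measured on the bait).  The bait itself is always a
    candidate, so the set is never empty.  Among candidates the winner
    maximizes, in order: structure quality (1/resolution - R-value, missing
    values ranking worst), release date (newer is better), length (longer is
    better), and finally smallest id.
    """
    members = sorted(cluster_members)
    if not members:
        raise ValueError("empty cluster")
    bait = medoid(members, graph)
    pool = set(universe) if universe is not None else set(members)
    tight = {bait}
    for m in pool:
        if m == bait:
            continue
        e = graph.edge(bait, m)
        if e is None:
            continue
        if e.identity >= tight_identity and e.coverage_of(bait) >= tight_coverage:
            tight.add(m)
    candidates = sorted(tight.intersection(members))
    best = candidates[0]
    best_key = _rank_key(entries[best])
    for c in candidates[1:]:
        key = _rank_key(entries[c])
        if key > best_key:
            best, best_key = c, key
    return best


def extract_validation_sets(
    entries: Mapping[str, StructureEntry],
    graph: IdentityGraph,
    cfg: SplitConfig,
) -> SplitResult:
    """Run the iterative validation-set extraction ladder.

    At each threshold, in ascending order, the entries still in play are
    clustered (transitive closure, no coverage requirement); clusters larger
    than ``cfg.max_cluster_size`` are not considered; up to
    ``cfg.clusters_per_level`` candidate clusters are drawn uniformly
    without replacement from a canonical ordering, so results depend only on
    the seed; each drawn cluster contributes one exemplar to the validation
    set and its other members to the removed set.  Entries left after the
    last level form the training pool.
    """
    if not entries:
        raise ValueError("empty entry set")
    rng = random.Random(cfg.seed)
    remaining = set(entries)
    validation: dict[float, list[str]] = {}
    removed: dict[float, list[str]] = {}
    levels_prov = []
    for t in cfg.thresholds:
        parts = cluster(graph, t, min_coverage=None, subset=remaining)
        candidates = [c for c in parts if len(c) <= cfg.max_cluster_size]
        k = min(cfg.clusters_per_level, len(candidates))
        if k < cfg.clusters_per_level:
            logger.warning(
                "level %s%%: only %d candidate clusters (requested %d)",
                t, len(candidates), cfg.clusters_per_level,
            )
        drawn = rng.sample(candidates, k) if k else []
        exemplars, dropped = [], []
        for c in drawn:
            ex = select_exemplar(
                c,
                entries,
                graph,
                cfg.exemplar_tight_identity,
                cfg.exemplar_tight_coverage,
                universe=remaining,
            )
            exemplars.append(ex)
            dropped.extend(m for m in c if m != ex)
            remaining.difference_update(c)
        validation[t] = sorted(exemplars)
        removed[t] = sorted(dropped)
        levels_prov.append(
            {
                "threshold": t,
                "n_clusters": len(parts),
                "n_candidates": len(candidates),
                "drawn_clusters": [list(c) for c in drawn],
            }
        )
    result = SplitResult(
        validation=validation,
        training_pool=sorted(remaining),
        removed=removed,
        provenance={"config": cfg.to_dict(), "seed": cfg.seed, "levels": levels_prov},
    )
    _check_partition(result, set(entries))
    return result


def _check_partition(result: SplitResult, universe: set[str]) -> None:
    parts = [result.all_validation_ids(), set(result.training_pool)]
    parts.extend(set(v) for v in result.removed.values())
    total = sum(len(p) for p in parts)
    union = set().union(*parts)
    if total != len(union) or union != universe:
        raise AssertionError("split result does not partition the input id set")


def make_thinnings(
    training_pool: Sequence[str],
    entries: Mapping[str, StructureEntry],
    graph: IdentityGraph,
    cfg: SplitConfig,
) -> dict[float, list[str]]:
    """Redundancy-reduced training subsets at each thinning level.

    Levels below 100% cluster the pool at that identity with the mutual
    coverage requirement ``cfg.thinning_coverage``; the 100% level groups
    exactly identical sequences.  One exemplar per cluster, selected with
    the same criteria as the validation exemplars.
    """
    if not training_pool:
        raise ValueError("empty training pool")
    pool = set(training_pool)
    out: dict[float, list[str]] = {}
    for level in cfg.thinning_levels:
        if level >= 100.0:
            groups: dict[str, list[str]] = {}
            for i in sorted(pool):
                groups.setdefault(entries[i].sequence, []).append(i)
            parts = sorted(groups.values(), key=lambda c: c[0])
        else:
            parts = cluster(graph, level, min_coverage=cfg.thinning_coverage, subset=pool)
        exemplars = [
            select_exemplar(
                c,
                entries,
                graph,
                cfg.exemplar_tight_identity,
                cfg.exemplar_tight_coverage,
                universe=pool,
            )
            for c in parts
        ]
        out[level] = sorted(exemplars)
    return out


# ---------------------------------------------------------------------------
# Manifest I/O


def write_split_manifest(result: SplitResult, sink: Union[str, Path, TextIO]) -> None:
    """Tab-separated manifest: one row per entry with its role.

    Columns: subset (``validation``/``training``), threshold (empty for
    training rows), entry id.  A provenance block (YAML, '#'-prefixed) echoes
    the configuration and seed.
    """
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        prov = {"config": result.provenance.get("config"), "seed": result.provenance.get("seed")}
        for line in yaml.safe_dump(prov, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        fh.write("subset\tthreshold\tid\n")
        for t in sorted(result.validation):
            for i in result.validation[t]:
                fh.write(f"validation\t{t:g}\t{i}\n")
        for i in result.training_pool:
            fh.write(f"training\t\t{i}\n")
    finally:
        if own:
            fh.close()


def read_split_manifest(source: Union[str, Path, TextIO]) -> tuple[dict[float, list[str]], list[str]]:
    """Read a split manifest back into (validation map, training ids)."""
    own = not hasattr(source, "read")
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    validation: dict[float, list[str]] = {}
    training: list[str] = []
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("subset\t"):
            continue
        subset, thr, eid = line.split("\t")
        if subset == "validation":
            validation.setdefault(float(thr), []).append(eid)
        else:
            training.append(eid)
    return validation, training


def write_removed_table(result: SplitResult, sink: Union[str, Path, TextIO]) -> None:
    """Tab-separated removed-member table: threshold, entry id."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("threshold\tid\n")
        for t in sorted(result.removed):
            for i in result.removed[t]:
                fh.write(f"{t:g}\t{i}\n")
    finally:
        if own:
            fh.close()


def write_thinning_tables(thinnings: Mapping[float, Sequence[str]], sink: Union[str, Path, TextIO]) -> None:
    """Tab-separated thinning membership: level, entry id."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("level\tid\n")
        for level in sorted(thinnings):
            for i in thinnings[level]:
                fh.write(f"{level:g}\t{i}\n")
    finally:
        if own:
            fh.close()
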