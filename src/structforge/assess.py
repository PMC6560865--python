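"""Distance of held-out entries to a training set, by maximum sequence identity.

For every validation or test entry, the assessment finds the entry's closest
training-set member under the pairwise backend, keeping only significant hits
(E-value at or below a cutoff, 0.001 by default).  Entries with no
significant hit are reported as 0% identity with an explicit
no-detectable-homology flag, so group medians over hit-free groups compute
as 0 rather than missing.  Group summaries are five-number summaries
(min, lower quartile, median, upper quartile, max).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from structforge.homology import (
    DEFAULT_EVALUE_THRESHOLD,
    IdentityGraph,
    SequenceBackend,
)

logger = logging.getLogger(__name__)


def max_identity_to_training(
    entry_id: str,
    training_ids: Iterable[str],
    scorer: Union[IdentityGraph, SequenceBackend],
    evalue_cutoff: float = DEFAULT_EVALUE_THRESHOLD,
) -> tuple[float, bool]:
    """Maximum percent identity of one entry to any training member.

    ``scorer`` is either a pre-built :class:`IdentityGraph` (whose edges are
    already significance-filtered) or a :class:`SequenceBackend` (pairs are
    computed on demand and filtered at ``evalue_cutoff``).  Returns
    ``(identity, has_hit)``; entries with no significant hit report
    ``(0.0, False)``.
    """
    training = [t for t in training_ids if t != entry_id]
    if not training:
        raise ValueError("training set is empty")
    best = 0.0
    hit = False
    for t in training:
        if isinstance(scorer, IdentityGraph):
            e = scorer.edge(entry_id, t)
            if e is None:
                continue
            if e.evalue is not None and e.evalue > evalue_cutoff:
                continue
        else:
            e = scorer.pair(entry_id, t)
            if e.evalue is not None and e.evalue > evalue_cutoff:
                continue
        hit = True
        best = max(best, e.identity)
    return best, hit


def assess_entries(
    query_ids: Iterable[str],
    training_ids: Sequence[str],
    scorer: Union[IdentityGraph, SequenceBackend],
    group: Union[str, Mapping[str, str]] = "all",
    evalue_cutoff: float = DEFAULT_EVALUE_THRESHOLD,
) -> pd.DataFrame:
    """Per-entry distance table: id, group, max_identity, has_hit.

    ``group`` is either a single label for all queries or a mapping from
    entry id to group label (e.g. the validation threshold the entry
    belongs to).
    """
    rows = []
    for q in query_ids:
        ident, hit = max_identity_to_training(q, training_ids, scorer, evalue_cutoff)
        g = group if isinstance(group, str) else group[q]
        rows.append({"id": q, "group": g, "max_identity": ident, "has_hit": hit})
    return pd.DataFrame(rows, columns=["id", "group", "max_identity", "has_hit"])


def summarize(per_entry: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of max_identity per group.

    Columns: group, n, min, q1, median, q3, max.  Empty groups are omitted
    with a warning.
    """
    rows = []
    for g, sub in per_entry.groupby("group", sort=True):
        vals = sub["max_identity"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("group %s is empty, omitted from summary", g)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": g,
                "n": int(vals.size),
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "min", "q1", "median", "q3", "max"])


def write_distance_table(per_entry: pd.DataFrame, sink: Union[str, Path, TextIO]) -> None:
    per_entry.to_csv(sink, sep="\t", index=False)


def write_summary_table(summary: pd.DataFrame, sink: Union[str, Path, TextIO]) -> None:
    summary.to_csv(sink, sep="\t", index=False)
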