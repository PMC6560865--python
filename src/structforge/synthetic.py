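"""Seeded synthetic corpora with controlled homology structure.

The generator emulates the statistical features the curation pipeline acts
on, without downloading anything: families of sequences at controlled
within-family identity (a random ancestor plus point-substituted
descendants), independent or weakly related ancestors across families,
release dates straddling a temporal cutoff, resolutions and R-values in
crystallographic ranges, smooth backbone-like coordinates with masked
missing fragments, and a per-entry MSA consisting of the family's sequences.

Mutations are substitution-only by default so the target identity maps
directly onto a point-mutation count; an optional deletion mode introduces
alignment gaps.  Coordinates are smooth synthetic curves, not physically
valid backbones — they exercise masks and serialization only.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from structforge.profiles import AA_ORDER, Alignment
from structforge.structures import StructureEntry, write_fasta, write_structure_table

_AA = np.array(list(AA_ORDER))


@dataclass
class FamilySpec:
    """Parameters of a synthetic corpus.

    ``within_identity`` is the target percent identity of each descendant to
    its family ancestor; ``between_identity`` caps relatedness across
    families (0 means independent random ancestors).  Dates are drawn
    uniformly from ``date_range``, resolutions from [1, 4] Angstroms and
    R-values from [0.15, 0.35], typical crystallographic ranges.
    """

    n_families: int = 40
    members_per_family: tuple[int, int] = (2, 5)
    within_identity: tuple[float, float] = (95.0, 99.0)
    between_identity: float = 0.0
    length: tuple[int, int] = (200, 300)
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2004, 1, 1), _dt.date(2008, 1, 1))
    missing_fraction: tuple[float, float] = (0.0, 0.10)
    seed: int = 0
    deletions: bool = False

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        lo, hi = self.within_identity
        if not (0 < lo <= hi <= 100):
            raise ValueError(f"infeasible within_identity target {self.within_identity}")
        if self.between_identity >= lo:
            raise ValueError("within_identity must exceed between_identity")
        if self.members_per_family[0] < 1 or self.members_per_family[0] > self.members_per_family[1]:
            raise ValueError("invalid members_per_family range")
        if self.length[0] < 2 or self.length[0] > self.length[1]:
            raise ValueError("invalid length range")
        f0, f1 = self.missing_fraction
        if not (0 <= f0 <= f1 < 1):
            raise ValueError("invalid missing_fraction range")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("empty date range")


@dataclass
class SyntheticCorpus:
    """Entries, per-entry MSAs, and the generating truth table."""

    entries: dict[str, StructureEntry]
    alignments: dict[str, Alignment]
    truth: pd.DataFrame  # columns: id, family, target_identity

    @property
    def sequences(self) -> dict[str, str]:
        return {i: e.sequence for i, e in self.entries.items()}

    def write(self, outdir: str | Path) -> None:
        """Write the corpus in the formats the other modules read:
        structure table, FASTA, one aligned-FASTA MSA per entry, truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = [self.entries[i] for i in sorted(self.entries)]
        write_structure_table(entries, outdir / "structures.tsv")
        write_fasta(entries, outdir / "sequences.fasta")
        msa_dir = outdir / "msa"
        msa_dir.mkdir(exist_ok=True)
        for eid in sorted(self.alignments):
            aln = self.alignments[eid]
            with open(msa_dir / f"{eid}.fasta", "w") as fh:
                for j, row in enumerate(aln.rows):
                    tag = "query" if j == aln.query_index else f"row{j}"
                    fh.write(f">{eid}|{tag}\n{row}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)])


def _mutate(rng: np.random.Generator, seq: str, target_identity: float) -> str:
    """Point-substitute a sequence down to the target percent identity."""
    L = len(seq)
    k = int(round(L * (1.0 - target_identity / 100.0)))
    out = list(seq)
    for pos in rng.choice(L, size=k, replace=False):
        old = out[pos]
        choices = [a for a in AA_ORDER if a != old]
        out[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _delete(rng: np.random.Generator, seq: str, n_del: int) -> tuple[str, np.ndarray]:
    keep = np.ones(len(seq), dtype=bool)
    if n_del:
        keep[rng.choice(len(seq), size=n_del, replace=False)] = False
    return "".join(c for c, k in zip(seq, keep) if k), keep


def _backbone(rng: np.random.Generator, length: int) -> np.ndarray:
    """A smooth helix-like curve, picometer integers, shape (L, 3, 3)."""
    t = np.arange(length, dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    ca = np.stack(
        [230 * np.cos(t * 1.75 + phase), 230 * np.sin(t * 1.75 + phase), 150 * t],
        axis=1,
    )
    n = ca + np.array([-120.0, 60.0, -90.0])
    c = ca + np.array([110.0, -70.0, 95.0])
    coords = np.stack([n, ca, c], axis=1)  # (L, 3 atoms, 3)
    return np.round(coords)


def _missing_mask(rng: np.random.Generator, length: int, fraction: float) -> np.ndarray:
    """Mask with `fraction` of residues unresolved, in 1-3 contiguous runs."""
    mask = np.ones(length, dtype=bool)
    n_missing = int(round(length * fraction))
    if n_missing == 0:
        return mask
    n_frags = int(rng.integers(1, 4))
    sizes = np.maximum(rng.multinomial(n_missing, np.ones(n_frags) / n_frags), 0)
    for size in sizes:
        size = int(size)
        if size == 0:
            continue
        start = int(rng.integers(0, max(length - size, 1)))
        mask[start : start + size] = False
    return mask


def generate_families(spec: FamilySpec) -> SyntheticCorpus:
    """Generate a corpus of sequence families with known ground truth.

    Each family consists of a random ancestor (member 0) and descendants
    point-mutated to a per-member target identity drawn from
    ``spec.within_identity``.  With ``between_identity > 0`` all family
    ancestors descend from one shared root at that identity; at 0 they are
    independent.  Every entry's MSA holds its whole family, with the entry
    itself as the query row.  Deterministic: the same spec yields
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    entries: dict[str, StructureEntry] = {}
    alignments: dict[str, Alignment] = {}
    truth_rows = []
    day_span = (spec.date_range[1] - spec.date_range[0]).days
    width = len(str(spec.n_families - 1))
    root = None
    if spec.between_identity > 0:
        root_len = int(rng.integers(spec.length[0], spec.length[1] + 1))
        root = _random_sequence(rng, root_len)

    for f in range(spec.n_families):
        if root is not None:
            ancestor = _mutate(rng, root, spec.between_identity)
        else:
            L = int(rng.integers(spec.length[0], spec.length[1] + 1))
            ancestor = _random_sequence(rng, L)
        L = len(ancestor)
        n_members = int(rng.integers(spec.members_per_family[0], spec.members_per_family[1] + 1))
        fam = f"F{f:0{width}d}"
        member_seqs: list[str] = []
        member_rows: list[str] = []  # rows in the ancestor coordinate frame
        targets: list[float] = []
        for m in range(n_members):
            if m == 0:
                seq, row, target = ancestor, ancestor, 100.0
            else:
                target = float(rng.uniform(*spec.within_identity))
                seq = _mutate(rng, ancestor, target)
                row = seq
                if spec.deletions:
                    n_del = int(rng.integers(0, max(L // 50, 1) + 1))
                    seq, keep = _delete(rng, seq, n_del)
                    row = "".join(c if k else "-" for c, k in zip(row, keep))
            member_seqs.append(seq)
            member_rows.append(row)
            targets.append(target)
        for m, (seq, target) in enumerate(zip(member_seqs, targets)):
            eid = f"{fam}_{m}"
            frac = float(rng.uniform(*spec.missing_fraction))
            mask = _missing_mask(rng, len(seq), frac)
            coords = _backbone(rng, len(seq))
            coords[~mask] = 0.0
            date = spec.date_range[0] + _dt.timedelta(days=int(rng.integers(0, day_span + 1)))
            entries[eid] = StructureEntry(
                id=eid,
                sequence=seq,
                coords=coords,
                mask=mask,
                release_date=date,
                resolution=float(np.round(rng.uniform(1.0, 4.0), 2)),
                r_value=float(np.round(rng.uniform(0.15, 0.35), 3)),
            )
            alignments[eid] = Alignment(eid, list(member_rows), query_index=m)
            truth_rows.append({"id": eid, "family": fam, "target_identity": target})
    truth = pd.DataFrame(truth_rows, columns=["id", "family", "target_identity"])
    return SyntheticCorpus(entries=entries, alignments=alignments, truth=truth)


def generate_contained_domain(
    long_length: int, domain_span: tuple[int, int], seed: int = 0
) -> tuple[StructureEntry, StructureEntry]:
    """A long entry plus a short entry equal to its subsequence.

    ``domain_span`` is 1-based inclusive.  The pair exercises the
    coverage-dependent clustering rule: locally the two match at 100%
    identity, but the alignment covers only part of the long entry.
    """
    start, end = domain_span
    if not (1 <= start <= end <= long_length):
        raise ValueError(f"span {domain_span} out of range for length {long_length}")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, long_length)
    date = _dt.date(2005, 6, 1)
    long_entry = StructureEntry(
        id="multi_domain",
        sequence=seq,
        coords=_backbone(rng, long_length),
        mask=np.ones(long_length, dtype=bool),
        release_date=date,
        resolution=2.0,
        r_value=0.2,
    )
    sub = seq[start - 1 : end]
    short_entry = StructureEntry(
        id="single_domain",
        sequence=sub,
        coords=_backbone(rng, len(sub)),
        mask=np.ones(len(sub), dtype=bool),
        release_date=date,
        resolution=2.0,
        r_value=0.2,
    )
    return long_entry, short_entry
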