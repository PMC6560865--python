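"""Weighted evolutionary profiles (PSSMs) from multiple sequence alignments.

A profile is built from an MSA in three steps: (i) optional greedy redundancy
filtering of alignment rows at a sequence-identity ceiling (Hobohm-1 style,
query always kept); (ii) Henikoff & Henikoff (1994) position-based sequence
weighting, so that clusters of near-identical rows collectively contribute no
more than a single diverse row; (iii) weighted per-column amino-acid
frequencies over the query columns, with per-column information content in
bits, ``log2(20) - H(column)``.

No pseudocounts are applied: a column with zero information content means the
alignment carries no signal there (empty or uniform column), which is exactly
the condition the drop rule tests for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
from Bio import AlignIO

#: Fixed amino-acid order of profile columns (alphabetical one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

GAP_CHARS = {"-", ".", "~"}

MAX_INFO_BITS = math.log2(20.0)

#: Absolute tolerance below which a column's information content counts as
#: zero; the entropy of a numerically uniform column is not exactly log2(20).
ZERO_INFO_TOL = 1e-12


@dataclass
class Alignment:
    """A multiple sequence alignment with a designated query row.

    Rows are equal-length strings over the 20 amino-acid letters, ``'X'``
    and gap characters.
    """

    id: str
    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.id}: empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError(f"{self.id}: ragged alignment rows")
        if not (0 <= self.query_index < len(self.rows)):
            raise ValueError(f"{self.id}: query index {self.query_index} out of range")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    def project_to_query(self) -> "Alignment":
        """Drop columns where the query row has a gap."""
        keep = [j for j, c in enumerate(self.query) if c not in GAP_CHARS]
        rows = ["".join(r[j] for j in keep) for r in self.rows]
        return Alignment(self.id, rows, self.query_index)


@dataclass
class Profile:
    """An MSA-derived weighted PSSM.

    ``freqs`` has shape ``(L, 20)`` in :data:`AA_ORDER`; each row sums to 1
    except at positions with no weighted residue mass (all-gap columns),
    which are all-zero and have zero information content.  ``info`` is the
    per-position information content in bits.
    """

    id: str
    freqs: np.ndarray
    info: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float).reshape(-1, 20)
        self.info = np.asarray(self.info, dtype=float).reshape(-1)
        if self.freqs.shape[0] != self.info.shape[0]:
            raise ValueError(f"{self.id}: freqs/info length mismatch")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def _row_identity(a: str, b: str) -> float:
    """Percent identity between two aligned rows: matches over columns where
    both rows are non-gap."""
    matches = 0
    aligned = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        aligned += 1
        if x == y:
            matches += 1
    return 100.0 * matches / aligned if aligned else 0.0


def redundancy_filter(aln: Alignment, max_identity: float = 90.0) -> Alignment:
    """Greedily drop alignment rows more than ``max_identity`` percent
    identical to an already retained row.

    The query row is always retained and considered first; the remaining
    rows are scanned in input order (Hobohm-1), so the result is
    deterministic for a given row order.  Output preserves input order.
    """
    if not 0 < max_identity <= 100:
        raise ValueError(f"max_identity must be in (0, 100], got {max_identity}")
    order = [aln.query_index] + [i for i in range(aln.n_rows) if i != aln.query_index]
    retained: list[int] = []
    for i in order:
        if i == aln.query_index:
            retained.append(i)
            continue
        if all(_row_identity(aln.rows[i], aln.rows[j]) <= max_identity for j in retained):
            retained.append(i)
    retained.sort()
    rows = [aln.rows[i] for i in retained]
    return Alignment(aln.id, rows, retained.index(aln.query_index))


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalized to 1.

    In each column, a residue of type ``t`` receives a share ``1/(r*s)``
    where ``r`` is the number of distinct residue types in the column and
    ``s`` the number of rows carrying type ``t``.  Gaps take no share and
    all-gap columns contribute nothing.  A row's weight is its summed share
    over columns, normalized across rows.
    """
    w = np.zeros(aln.n_rows, dtype=float)
    for j in range(aln.n_cols):
        col = [r[j] for r in aln.rows]
        counts: dict[str, int] = {}
        for c in col:
            if c not in GAP_CHARS:
                counts[c] = counts.get(c, 0) + 1
        r_types = len(counts)
        if r_types == 0:
            continue
        for i, c in enumerate(col):
            if c not in GAP_CHARS:
                w[i] += 1.0 / (r_types * counts[c])
    total = w.sum()
    if total == 0.0:
        # degenerate all-gap alignment: fall back to uniform weights
        return np.full(aln.n_rows, 1.0 / aln.n_rows)
    return w / total


def compute_profile(aln: Alignment, weights: Sequence[float] | None = None) -> Profile:
    """Weighted PSSM over the query columns of an alignment.

    ``freqs[p, a]`` is the weighted fraction of residue ``a`` among non-gap
    residues at query column ``p`` (letters outside the 20-letter alphabet,
    i.e. ``'X'``, are ignored).  ``info[p] = log2(20) - H(freqs[p])`` bits,
    and 0 where the column has no weighted residue mass.
    """
    if weights is None:
        weights = henikoff_weights(aln)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != aln.n_rows:
        raise ValueError(
            f"{aln.id}: {weights.shape[0]} weights for {aln.n_rows} rows"
        )
    proj = aln.project_to_query()
    L = proj.n_cols
    freqs = np.zeros((L, 20), dtype=float)
    for i, row in enumerate(proj.rows):
        wi = weights[i]
        for p, c in enumerate(row):
            k = _AA_INDEX.get(c)
            if k is not None:
                freqs[p, k] += wi
    info = np.zeros(L, dtype=float)
    for p in range(L):
        total = freqs[p].sum()
        if total <= 0.0:
            freqs[p] = 0.0
            continue
        freqs[p] /= total
        nz = freqs[p][freqs[p] > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info[p] = max(MAX_INFO_BITS - entropy, 0.0)
    return Profile(aln.id, freqs, info)


def resolve_sequence(sequence: str, profile: Profile) -> str:
    """Replace each ``'X'`` (unknown or chemically modified residue) with the
    most probable residue of the profile at that position.

    Ties are broken by alphabetical one-letter code; an all-zero column
    therefore resolves to ``'A'``.  Idempotent: non-``'X'`` positions pass
    through unchanged.
    """
    if len(sequence) != profile.length:
        raise ValueError(
            f"sequence length {len(sequence)} != profile length {profile.length}"
        )
    out = list(sequence)
    for p, c in enumerate(sequence):
        if c == "X":
            out[p] = AA_ORDER[int(np.argmax(profile.freqs[p]))]
    return "".join(out)


def should_drop(profile: Profile, max_zero_run: int = 3, tol: float = ZERO_INFO_TOL) -> bool:
    """True iff the profile contains a run of strictly more than
    ``max_zero_run`` consecutive positions with zero information content —
    a strong indicator that the sequence cannot be faithfully resolved."""
    run = 0
    for v in profile.info:
        if v <= tol:
            run += 1
            if run > max_zero_run:
                return True
        else:
            run = 0
    return False


# ---------------------------------------------------------------------------
# I/O


def read_msa(source: Union[str, Path, TextIO], fmt: str | None = None, query_id: str | None = None) -> Alignment:
    """Read an MSA from aligned FASTA or Stockholm.

    The format is inferred from the file content when not given.  The query
    row defaults to the first row, or to the row named ``query_id``.
    """
    own = not hasattr(source, "read")
    fh = open(source) if own else source
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    if fmt is None:
        fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    from io import StringIO

    msa = AlignIO.read(StringIO(text), fmt)
    rows = [str(rec.seq) for rec in msa]
    ids = [rec.id for rec in msa]
    qi = 0
    if query_id is not None:
        qi = ids.index(query_id)
    name = query_id or (ids[0] if ids else "msa")
    return Alignment(name, rows, qi)


def write_pssm(profile: Profile, sink: Union[str, Path, TextIO]) -> None:
    """Write a profile as a tab-separated PSSM table.

    Header line, then one row per position: 1-based position index, the 20
    amino-acid frequencies in :data:`AA_ORDER`, and the information content
    (bits), all to 5 decimal places.
    """
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("pos\t" + "\t".join(AA_ORDER) + "\tinfo\n")
        for p in range(profile.length):
            vals = "\t".join(f"{v:.5f}" for v in profile.freqs[p])
            fh.write(f"{p + 1}\t{vals}\t{profile.info[p]:.5f}\n")
    finally:
        if own:
            fh.close()


def read_pssm(source: Union[str, Path, TextIO], id: str = "pssm") -> Profile:
    """Read a PSSM table written by :func:`write_pssm`."""
    own = not hasattr(source, "read")
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    freqs, info = [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        freqs.append([float(v) for v in parts[1:21]])
        info.append(float(parts[21]))
    return Profile(id, np.array(freqs), np.array(info))
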