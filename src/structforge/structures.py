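"""Structure ingestion, normalization, and filtering.

Entries are physical polypeptide chains carrying a primary sequence, backbone
coordinates (N, C-alpha, C' per residue, in picometers), a resolved-residue
mask, and experimental metadata (public release date, resolution, R-value).
Two input formats are supported: a subset of mmCIF (parsed with gemmi) and a
simplified tab-separated structure table used for fixtures and interchange.

Conventions:

* Residue positions exposed to callers (domain boundaries) are 1-based and
  inclusive on both ends; internal arrays are 0-based.
* Coordinates are integers or floats in picometers; positions that are not
  resolved in the experiment carry the placeholder (0, 0, 0) and the mask is
  authoritative.
* Chemically modified or unknown residues are recorded as ``'X'`` at
  ingestion; substituting them with the most probable profile residue is the
  profiles module's job, since the PSSM does not exist at parse time.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel quality for structures lacking resolution or R-value: they rank
#: below any structure for which the quality criterion is defined.
WORST_QUALITY = float("-inf")

#: Start dates of CASP experiments 7-12, usable as temporal cutoffs.
CASP_CUTOFF_DATES = {
    7: _dt.date(2006, 5, 13),
    8: _dt.date(2008, 5, 5),
    9: _dt.date(2010, 5, 3),
    10: _dt.date(2012, 5, 1),
    11: _dt.date(2014, 5, 1),
    12: _dt.date(2016, 5, 1),
}

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed, naming the offending record."""


def parse_cutoff_date(text: Union[str, _dt.date]) -> _dt.date:
    """Parse a cutoff date given as ``YYYY/M/D``, ``YYYY-MM-DD`` or a date.

    The slash form accepts non-zero-padded months and days, so historical
    CASP start dates such as ``2006/5/13`` are accepted verbatim.
    """
    if isinstance(text, _dt.date):
        return text
    m = re.fullmatch(r"(\d{4})[/-](\d{1,2})[/-](\d{1,2})", text.strip())
    if not m:
        raise FormatError(f"unparseable cutoff date: {text!r}")
    return _dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))


@dataclass
class StructureEntry:
    """One physical polypeptide chain.

    Attributes
    ----------
    id:
        Source identifier plus chain label, e.g. ``"1XYZ_A"``.
    sequence:
        Amino-acid string over the 20 one-letter codes plus ``'X'``.
    coords:
        Array of shape ``(L, 3, 3)``: per residue the N, C-alpha and C'
        positions, each an (x, y, z) triple in picometers.  Placeholder
        zeros where the mask is false.
    mask:
        Boolean vector of length ``L``; true marks resolved residues.
    release_date:
        Public release date, or None when unknown.
    resolution:
        Crystallographic resolution in Angstroms, or None.
    r_value:
        Dimensionless R-value in [0, 1], or None.
    """

    id: str
    sequence: str
    coords: np.ndarray
    mask: np.ndarray
    release_date: _dt.date | None = None
    resolution: float | None = None
    r_value: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3, 3)
        self.mask = np.asarray(self.mask, dtype=bool)
        L = len(self.sequence)
        if not (self.coords.shape[0] == L == self.mask.shape[0]):
            raise ValueError(
                f"{self.id}: inconsistent lengths (sequence {L}, "
                f"coords {self.coords.shape[0]}, mask {self.mask.shape[0]})"
            )
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_unresolved(self) -> int:
        return int((~self.mask).sum())

    @property
    def quality(self) -> float:
        return quality_score(self.resolution, self.r_value)


@dataclass(frozen=True)
class DomainBoundary:
    """A contiguous domain on a chain, 1-based and inclusive on both ends."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain boundary {self.start}..{self.end}")


def quality_score(resolution: float | None, r_value: float | None) -> float:
    """Structure quality, ``1/resolution - R-value`` (the PDB's criterion).

    Structures missing either value receive :data:`WORST_QUALITY` so that
    they rank below any structure for which the criterion is defined.
    """
    if resolution is None or r_value is None:
        return WORST_QUALITY
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    return 1.0 / resolution - r_value


def passes_inclusion_filter(entry: StructureEntry) -> bool:
    """True unless the entry has fewer than two residues or more than 90%
    of its residues unresolved.  Exactly 90% unresolved still passes (the
    exclusion rule is a strict inequality)."""
    if entry.length < 2:
        return False
    return entry.n_unresolved / entry.length <= 0.90


def extract_domain(entry: StructureEntry, boundary: DomainBoundary) -> StructureEntry:
    """Slice out a single-domain entry at a 1-based inclusive boundary.

    The id is suffixed with the boundary; metadata is inherited.
    """
    if boundary.end > entry.length:
        raise IndexError(
            f"{entry.id}: boundary {boundary.start}..{boundary.end} exceeds "
            f"length {entry.length}"
        )
    lo, hi = boundary.start - 1, boundary.end  # half-open internal slice
    return replace(
        entry,
        id=f"{entry.id}_{boundary.start}-{boundary.end}",
        sequence=entry.sequence[lo:hi],
        coords=entry.coords[lo:hi].copy(),
        mask=entry.mask[lo:hi].copy(),
    )


def temporal_filter(
    entries: Iterable[StructureEntry],
    cutoff: Union[str, _dt.date],
    strict: bool = False,
) -> list[StructureEntry]:
    """Keep entries publicly released strictly before the cutoff date.

    Entries without a release date are rejected with a warning by default;
    with ``strict=True`` they raise instead.  Input order is preserved.
    """
    cutoff = parse_cutoff_date(cutoff)
    kept = []
    for e in entries:
        if e.release_date is None:
            if strict:
                raise ValueError(f"{e.id}: missing release date")
            logger.warning("%s: missing release date, rejected by temporal filter", e.id)
            continue
        if e.release_date < cutoff:
            kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# mmCIF ingestion


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code in VALID_RESIDUES else "X"


def _block_value(block: gemmi.cif.Block, tags: Sequence[str]) -> str | None:
    for tag in tags:
        v = block.find_value(tag)
        if v not in (None, "?", "."):
            return gemmi.cif.as_string(v)
    return None


def _block_metadata(block: gemmi.cif.Block):
    res = _block_value(block, ["_refine.ls_d_res_high", "_reflns.d_resolution_high"])
    rv = _block_value(
        block, ["_refine.ls_R_factor_obs", "_refine.ls_R_factor_R_work"]
    )
    date = None
    for tag in (
        "_pdbx_audit_revision_history.revision_date",
        "_database_PDB_rev.date_original",
        "_pdbx_database_status.recvd_initial_deposition_date",
    ):
        col = block.find_loop(tag)
        vals = [gemmi.cif.as_string(v) for v in col] if col else []
        v = _block_value(block, [tag])
        if v:
            vals.append(v)
        vals = [v for v in vals if v not in ("?", ".")]
        if vals:
            date = min(_dt.date.fromisoformat(v) for v in vals)
            break
    return (
        float(res) if res is not None else None,
        float(rv) if rv is not None else None,
        date,
    )


def read_mmcif(source: Union[str, Path], id_prefix: str | None = None) -> list[StructureEntry]:
    """Parse an mmCIF file (or mmCIF text) into one entry per physical chain.

    Only the first model is used.  Logical chains that belong to the same
    physical polypeptide chain (same author chain) are concatenated in
    residue-number order, with numbering gaps filled by ``'X'`` residues
    masked false.  Residues missing any of N/C-alpha/C' are masked false.
    """
    text = None
    path = Path(source) if isinstance(source, Path) else None
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith("data_"):
            text = source
        else:
            path = Path(source)
    try:
        if text is not None:
            doc = gemmi.cif.read_string(text)
        else:
            doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        st = gemmi.make_structure_from_block(block)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable mmCIF input: {exc}") from exc

    resolution, r_value, release_date = _block_metadata(block)
    prefix = id_prefix or (st.name or "entry").strip() or "entry"
    if len(st) == 0:
        raise FormatError(f"{prefix}: mmCIF contains no models")
    model = st[0]  # first-model rule

    entries = []
    for chain in model:
        residues = [r for r in chain if _is_polymer_residue(r)]
        if not residues:
            logger.warning("%s chain %s: zero residues, skipped", prefix, chain.name)
            continue
        residues.sort(key=lambda r: r.seqid.num)
        first, last = residues[0].seqid.num, residues[-1].seqid.num
        L = last - first + 1
        seq = ["X"] * L
        mask = np.zeros(L, dtype=bool)
        coords = np.zeros((L, 3, 3), dtype=float)
        for r in residues:
            i = r.seqid.num - first
            seq[i] = _one_letter(r.name)
            triple = [r.find_atom(a, "*") for a in ("N", "CA", "C")]
            if all(a is not None for a in triple):
                mask[i] = True
                for k, a in enumerate(triple):
                    # mmCIF coordinates are Angstroms; store picometers
                    coords[i, k] = (a.pos.x * 100.0, a.pos.y * 100.0, a.pos.z * 100.0)
        entries.append(
            StructureEntry(
                id=f"{prefix}_{chain.name}",
                sequence="".join(seq),
                coords=coords,
                mask=mask,
                release_date=release_date,
                resolution=resolution,
                r_value=r_value,
            )
        )
    return entries


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_water():
        return False
    # keep amino acids and unknown residues that carry backbone atoms
    if info is not None and info.is_amino_acid():
        return True
    return res.find_atom("CA", "*") is not None


# ---------------------------------------------------------------------------
# Simplified structure table (tab-separated fixture/interchange format)
#
# Columns: id, release_date (ISO or empty), resolution (or empty), r_value
# (or empty), sequence, mask ('+'/'-'), coords (9L space-separated picometer
# values: N,CA,C' x,y,z per residue, zeros where masked).

TABLE_COLUMNS = ["id", "release_date", "resolution", "r_value", "sequence", "mask", "coords"]


def read_structure_table(source: Union[str, Path, TextIO]) -> list[StructureEntry]:
    """Read the simplified tab-separated structure table."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<stream>")
    else:
        name = str(source)
        lines = Path(source).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != TABLE_COLUMNS:
        raise FormatError(f"{name}: bad structure-table header {header}")
    entries = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(TABLE_COLUMNS):
            raise FormatError(f"{name}:{ln}: expected {len(TABLE_COLUMNS)} columns")
        eid, rdate, res, rv, seq, mask_s, coords_s = parts
        try:
            L = len(seq)
            mask = np.array([c == "+" for c in mask_s], dtype=bool)
            vals = (
                np.array(coords_s.split(), dtype=float) if coords_s.strip() else np.zeros(0)
            )
            coords = vals.reshape(L, 3, 3)
            entries.append(
                StructureEntry(
                    id=eid,
                    sequence=seq,
                    coords=coords,
                    mask=mask,
                    release_date=_dt.date.fromisoformat(rdate) if rdate else None,
                    resolution=float(res) if res else None,
                    r_value=float(rv) if rv else None,
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{name}:{ln} ({eid}): {exc}") from exc
    return entries


def write_structure_table(entries: Iterable[StructureEntry], sink: Union[str, Path, TextIO]) -> None:
    """Write entries as the simplified tab-separated structure table."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for e in entries:
            flat = e.coords.reshape(-1)
            coords_s = " ".join(_fmt_num(v) for v in flat)
            fh.write(
                "\t".join(
                    [
                        e.id,
                        e.release_date.isoformat() if e.release_date else "",
                        _fmt_num(e.resolution) if e.resolution is not None else "",
                        _fmt_num(e.r_value) if e.r_value is not None else "",
                        e.sequence,
                        "".join("+" if m else "-" for m in e.mask),
                        coords_s,
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def _fmt_num(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def ingest_structure(source: Union[str, Path, TextIO]) -> list[StructureEntry]:
    """Ingest a structure input, dispatching on format.

    mmCIF inputs (``.cif`` path or text starting with ``data_``) go through
    :func:`read_mmcif`; anything else is read as the simplified structure
    table.
    """
    if hasattr(source, "read"):
        return read_structure_table(source)
    s = str(source)
    if "\n" in s and not isinstance(source, Path):
        head = s.lstrip()
        if head.startswith("data_") or head.startswith("#"):
            return read_mmcif(s)
        raise FormatError("inline text input is not mmCIF (no data_ block)")
    path = Path(s)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        return read_mmcif(path)
    return read_structure_table(path)


def read_domain_table(source: Union[str, Path, TextIO]) -> list[DomainBoundary]:
    """Read a domain-boundary table: chain_id, start, end (tab-separated,
    1-based inclusive), with or without a header line."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    out = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if ln == 1 and parts[0].lower() in {"chain_id", "chain", "id"}:
            continue
        if len(parts) < 3:
            raise FormatError(f"domain table line {ln}: expected 3 columns")
        try:
            out.append(DomainBoundary(parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise FormatError(f"domain table line {ln}: {exc}") from exc
    return out


def write_fasta(entries: Iterable[StructureEntry], sink: Union[str, Path, TextIO]) -> None:
    """Write entry sequences as FASTA (60-column wrapped)."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        for e in entries:
            fh.write(f">{e.id}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")
    finally:
        if own:
            fh.close()


def write_mask_table(entries: Iterable[StructureEntry], sink: Union[str, Path, TextIO]) -> None:
    """Write the per-entry mask records: id TAB '+'/'-' string."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        for e in entries:
            fh.write(f"{e.id}\t" + "".join("+" if m else "-" for m in e.mask) + "\n")
    finally:
        if own:
            fh.close()
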