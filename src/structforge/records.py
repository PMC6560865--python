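"""The unified text record format: sequence + profile + structure per entry.

Each record is a sequence of bracket-tagged sections in fixed order::

    [ID]            one line, the entry id
    [PRIMARY]       one line, the primary amino-acid sequence (length L)
    [EVOLUTIONARY]  21 lines: 20 amino-acid frequency rows in alphabetical
                    one-letter order, then the information-content row; each
                    line holds L tab-separated values to 5 decimal places
    [SECONDARY]     optional, one line: 8-letter per-residue annotation;
                    preserved on read, never synthesized
    [TERTIARY]      3 lines (x, y, z): 3L tab-separated picometer values,
                    residue-major N, C-alpha, C' triples
    [MASK]          one line of '+'/'-' (resolved / unresolved)

followed by a blank line.  Numbers are printed in a fixed format so that
identical records serialize to identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

import numpy as np

from structforge.profiles import Profile
from structforge.structures import StructureEntry

SECTION_ORDER = ["[ID]", "[PRIMARY]", "[EVOLUTIONARY]", "[TERTIARY]", "[MASK]"]


class RecordError(ValueError):
    """Raised on malformed record text, carrying the record id and line."""


@dataclass
class UnifiedRecord:
    """One entry's sequence, evolutionary profile, tertiary trace, and mask.

    ``tertiary`` has shape ``(3, 3L)``: rows are x, y, z; columns are the
    N, C-alpha, C' atoms of residue 0, then residue 1, and so on, in
    picometers.  Unresolved residues carry placeholder zeros; ``mask`` is
    authoritative.
    """

    id: str
    primary: str
    evolutionary: Profile
    tertiary: np.ndarray
    mask: str
    secondary: str | None = None

    def __post_init__(self) -> None:
        self.tertiary = np.asarray(self.tertiary, dtype=float).reshape(3, -1)
        self.validate()

    def validate(self) -> None:
        L = len(self.primary)
        if L == 0:
            raise ValueError(f"{self.id}: empty record")
        if self.evolutionary.length != L:
            raise ValueError(
                f"{self.id}: profile length {self.evolutionary.length} != {L}"
            )
        if self.tertiary.shape != (3, 3 * L):
            raise ValueError(
                f"{self.id}: tertiary shape {self.tertiary.shape} != (3, {3 * L})"
            )
        if len(self.mask) != L or set(self.mask) - {"+", "-"}:
            raise ValueError(f"{self.id}: bad mask")
        if self.secondary is not None and len(self.secondary) != L:
            raise ValueError(f"{self.id}: secondary length mismatch")
        # the mask is authoritative: '+' residues must carry coordinates,
        # '-' residues the (0,0,0) placeholder
        triples = self.tertiary.reshape(3, L, 3)
        nonzero = np.any(triples != 0.0, axis=(0, 2))
        plus = np.array([c == "+" for c in self.mask])
        if np.any(nonzero & ~plus):
            raise ValueError(f"{self.id}: coordinates present at masked positions")

    @property
    def length(self) -> int:
        return len(self.primary)

    @classmethod
    def from_parts(
        cls, entry: StructureEntry, profile: Profile, secondary: str | None = None
    ) -> "UnifiedRecord":
        """Assemble a record from a structure entry and its profile."""
        L = entry.length
        tertiary = np.transpose(entry.coords.reshape(L * 3, 3))  # -> (3, 3L)
        return cls(
            id=entry.id,
            primary=entry.sequence,
            evolutionary=profile,
            tertiary=tertiary,
            mask="".join("+" if m else "-" for m in entry.mask),
            secondary=secondary,
        )


def write_record(rec: UnifiedRecord, sink: Union[str, Path, TextIO]) -> None:
    """Serialize one record; refuses to write an invariant-violating record."""
    rec.validate()
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("[ID]\n" + rec.id + "\n")
        fh.write("[PRIMARY]\n" + rec.primary + "\n")
        fh.write("[EVOLUTIONARY]\n")
        for row in rec.evolutionary.freqs.T:  # 20 rows of L values
            fh.write("\t".join(f"{v:.5f}" for v in row) + "\n")
        fh.write("\t".join(f"{v:.5f}" for v in rec.evolutionary.info) + "\n")
        if rec.secondary is not None:
            fh.write("[SECONDARY]\n" + rec.secondary + "\n")
        fh.write("[TERTIARY]\n")
        for row in rec.tertiary:
            fh.write("\t".join(f"{v:.1f}" for v in row) + "\n")
        fh.write("[MASK]\n" + rec.mask + "\n")
        fh.write("\n")
    finally:
        if own:
            fh.close()


def write_records(recs: Iterable[UnifiedRecord], sink: Union[str, Path, TextIO]) -> None:
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        for rec in recs:
            write_record(rec, fh)
    finally:
        if own:
            fh.close()


class _LineReader:
    def __init__(self, fh: TextIO):
        self.fh = fh
        self.lineno = 0
        self._pushback: list[str] = []

    def next_line(self) -> str | None:
        if self._pushback:
            self.lineno += 1
            return self._pushback.pop()
        line = self.fh.readline()
        if line == "":
            return None
        self.lineno += 1
        return line.rstrip("\n").rstrip()

    def push(self, line: str) -> None:
        self._pushback.append(line)
        self.lineno -= 1


def read_record(source: TextIO | "_LineReader") -> UnifiedRecord | None:
    """Parse one record from a text stream; None at end of stream.

    Strict about section order (``[SECONDARY]`` optionally between
    ``[EVOLUTIONARY]`` and ``[TERTIARY]``), tolerant of trailing whitespace
    and blank lines between records.
    """
    rd = source if isinstance(source, _LineReader) else _LineReader(source)

    def fail(msg: str, rec_id: str = "?") -> RecordError:
        return RecordError(f"record {rec_id}, line {rd.lineno}: {msg}")

    # skip blank separator lines
    line = rd.next_line()
    while line is not None and line == "":
        line = rd.next_line()
    if line is None:
        return None
    if line != "[ID]":
        raise fail(f"expected [ID], got {line!r}")
    rec_id = _require_line(rd, fail, "[ID]")

    def expect(tag: str) -> None:
        got = rd.next_line()
        if got != tag:
            raise fail(f"expected {tag}, got {got!r}", rec_id)

    expect("[PRIMARY]")
    primary = _require_line(rd, fail, "[PRIMARY]", rec_id)
    L = len(primary)

    expect("[EVOLUTIONARY]")
    ev_rows = []
    for k in range(21):
        row = _require_line(rd, fail, "[EVOLUTIONARY]", rec_id)
        vals = row.split("\t")
        if len(vals) != L:
            raise fail(
                f"[EVOLUTIONARY] row {k + 1} has {len(vals)} values, expected {L}",
                rec_id,
            )
        try:
            ev_rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise fail(f"[EVOLUTIONARY]: {exc}", rec_id)
    ev = np.array(ev_rows)
    profile = Profile(rec_id, ev[:20].T, ev[20])

    line = rd.next_line()
    secondary = None
    if line == "[SECONDARY]":
        secondary = _require_line(rd, fail, "[SECONDARY]", rec_id)
        line = rd.next_line()
    if line != "[TERTIARY]":
        raise fail(f"expected [TERTIARY], got {line!r}", rec_id)
    tert_rows = []
    for k in range(3):
        row = _require_line(rd, fail, "[TERTIARY]", rec_id)
        vals = row.split("\t")
        if len(vals) != 3 * L:
            raise fail(
                f"[TERTIARY] row {k + 1} has {len(vals)} values, expected {3 * L}",
                rec_id,
            )
        try:
            tert_rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise fail(f"[TERTIARY]: {exc}", rec_id)

    expect("[MASK]")
    mask = _require_line(rd, fail, "[MASK]", rec_id)

    try:
        return UnifiedRecord(
            id=rec_id,
            primary=primary,
            evolutionary=profile,
            tertiary=np.array(tert_rows),
            mask=mask,
            secondary=secondary,
        )
    except ValueError as exc:
        raise fail(str(exc), rec_id)


def _require_line(rd: _LineReader, fail, section: str, rec_id: str = "?") -> str:
    line = rd.next_line()
    if line is None or line == "":
        raise fail(f"truncated {section} section", rec_id)
    return line


def read_records(source: Union[str, Path, TextIO]) -> Iterator[UnifiedRecord]:
    """Iterate over all records in a file or stream."""
    own = not hasattr(source, "read")
    fh = open(source) if own else source
    rd = _LineReader(fh)
    try:
        while True:
            rec = read_record(rd)
            if rec is None:
                return
            yield rec
    finally:
        if own:
            fh.close()
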