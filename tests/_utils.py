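"""Shared helpers and independent oracles for the test suite."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
from Bio.Align import substitution_matrices

from structforge.profiles import AA_ORDER, Profile
from structforge.records import UnifiedRecord
from structforge.structures import StructureEntry

B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def make_entry(
    eid: str,
    sequence: str,
    mask=None,
    date: dt.date = dt.date(2005, 1, 1),
    resolution: float | None = 2.0,
    r_value: float | None = 0.2,
) -> StructureEntry:
    """A structurally consistent entry with synthetic nonzero coordinates at
    resolved positions."""
    L = len(sequence)
    mask = np.ones(L, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    coords = np.zeros((L, 3, 3))
    for i in range(L):
        if mask[i]:
            for k in range(3):
                coords[i, k] = (100 * (i + 1), 200 * (k + 1), 300)
    return StructureEntry(
        id=eid,
        sequence=sequence,
        coords=coords,
        mask=mask,
        release_date=date,
        resolution=resolution,
        r_value=r_value,
    )


def sw_score_oracle(a: str, b: str, open_=11.0, extend=1.0) -> float:
    """Brute-force Gotoh local alignment score (BLOSUM62, affine gaps).

    Gap convention matches the production aligner: a gap of length k costs
    open_ + (k - 1) * extend.  Intended for short sequences only.
    """
    m, n = len(a), len(b)
    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in b (consumes a)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in a (consumes b)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = B62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0) + s
            Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - extend, Iy[i - 1, j] - open_)
            Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - extend, Ix[i, j - 1] - open_)
            best = max(best, M[i, j])
    return best


def transitive_closure_partition(nodes, edges) -> set[frozenset]:
    """Connected components by repeated boolean matrix squaring."""
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.eye(n, dtype=bool)
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = True
    while True:
        A2 = A @ A
        if np.array_equal(A2, A):
            break
        A = A2
    parts = {}
    for i in range(n):
        key = tuple(np.flatnonzero(A[i]))
        parts[key] = frozenset(nodes[j] for j in key)
    return set(parts.values())


def random_profile(rng: np.random.Generator, L: int) -> Profile:
    freqs = rng.dirichlet(np.ones(20), size=L)
    freqs = np.round(freqs, 5)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    nz = np.where(freqs > 0, freqs, 1.0)
    info = np.maximum(np.log2(20.0) + (freqs * np.log2(nz)).sum(axis=1), 0.0)
    return Profile("p", freqs, info)


def random_record(rng: np.random.Generator, L: int, mask_mode: str = "random") -> UnifiedRecord:
    """A random but internally consistent unified record.

    ``mask_mode``: 'random', 'all_masked' (every residue unresolved) or
    'none_masked'.
    """
    letters = np.array(list(AA_ORDER))
    primary = "".join(letters[rng.integers(0, 20, size=L)])
    if mask_mode == "all_masked":
        mask = np.zeros(L, dtype=bool)
    elif mask_mode == "none_masked":
        mask = np.ones(L, dtype=bool)
    else:
        mask = rng.random(L) < 0.8
    tert = np.zeros((3, 3 * L))
    for i in range(L):
        if mask[i]:
            tert[:, 3 * i : 3 * i + 3] = rng.integers(-50000, 50000, size=(3, 3))
    return UnifiedRecord(
        id=f"R{rng.integers(0, 10 ** 9)}",
        primary=primary,
        evolutionary=random_profile(rng, L),
        tertiary=tert,
        mask="".join("+" if m else "-" for m in mask),
    )


def mmcif_text(
    atoms,
    resolution: float | None = 2.0,
    r_value: float | None = 0.20,
    dates=("2006-01-15",),
    name: str = "test1",
) -> str:
    """Build minimal mmCIF text.

    ``atoms`` is a list of tuples (atom_name, comp3, label_asym, entity,
    label_seq, auth_seq, auth_asym, x, y, z, model).
    """
    out = [f"data_{name}"]
    if resolution is not None:
        out.append(f"_refine.ls_d_res_high {resolution}")
    if r_value is not None:
        out.append(f"_refine.ls_R_factor_obs {r_value}")
    if dates:
        out.append("loop_")
        out.append("_pdbx_audit_revision_history.ordinal")
        out.append("_pdbx_audit_revision_history.revision_date")
        for i, d in enumerate(dates, 1):
            out.append(f"{i} {d}")
    out += [
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    for k, (aname, comp, lasym, ent, lseq, aseq, aasym, x, y, z, model) in enumerate(atoms, 1):
        elem = aname[0]
        out.append(
            f"ATOM {k} {elem} {aname} . {comp} {lasym} {ent} {lseq} ? "
            f"{x} {y} {z} 1.0 10.0 {aseq} {aasym} {model}"
        )
    return "\n".join(out) + "\n"


def residue_atoms(comp3, label_asym, entity, seq, auth_asym, base, model=1, drop=()):
    """Atoms (N, CA, C) for one residue, omitting names in ``drop``."""
    rows = []
    for k, aname in enumerate(("N", "CA", "C")):
        if aname in drop:
            continue
        rows.append(
            (aname, comp3, label_asym, entity, seq, seq, auth_asym,
             base + k, base + 10 * seq, float(model), model)
        )
    return rows
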