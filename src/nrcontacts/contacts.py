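"""Binary contact maps, residue–ligand contact vectors, contact frequencies.

A residue–residue contact is formed when the minimum distance between atoms
of the two residues is within the cutoff (closed bound: exactly 4.5 Å counts
as a contact).  Crystal-ensemble analysis uses heavy atoms at 4.5 Å;
simulation snapshots use all atoms, hydrogens included, at 4.2 Å.
Sequential neighbours (|i−j| ≤ 2 in author numbering) are never counted as
contacts; the separation is evaluated on author numbering, so a gap of
unresolved residues does not re-admit neighbouring pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree

from .errors import EnsembleError, WindowError
from .structure_io import Structure, strip_hydrogens

HEAVY_CUTOFF = 4.5  #: Å, crystal structures, heavy atoms only
ALL_ATOM_CUTOFF = 4.2  #: Å, simulation snapshots, hydrogens included
MIN_SEQ_SEP = 3  #: contacts require |i−j| ≥ 3
COMMON_WINDOW = (276, 475)  #: shared analysis window across crystal entries


@dataclass(frozen=True)
class ContactMatrix:
    """Binary symmetric residue–residue contact map on window [lo, hi]."""

    lo: int
    hi: int
    entries: np.ndarray  # (n, n) uint8, n = hi - lo + 1
    cutoff: float
    min_seq_sep: int = MIN_SEQ_SEP
    hydrogen_policy: str = "heavy_only"  # heavy_only | all_atom
    structure_id: str = ""

    def __post_init__(self):
        n = self.hi - self.lo + 1
        e = np.asarray(self.entries, dtype=np.uint8)
        if self.lo > self.hi:
            raise WindowError(f"invalid window [{self.lo}, {self.hi}]")
        if e.shape != (n, n):
            raise WindowError(f"entries shape {e.shape} does not match window size {n}")
        if not np.array_equal(e, e.T):
            raise WindowError("contact matrix must be symmetric")
        if e.max(initial=0) > 1:
            raise WindowError("contact matrix entries must be binary")
        object.__setattr__(self, "entries", e)

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    def contact_pairs(self) -> list[tuple[int, int]]:
        """Unordered contact pairs (i < j) in author numbering."""
        ii, jj = np.nonzero(np.triu(self.entries, k=1))
        return [(int(i) + self.lo, int(j) + self.lo) for i, j in zip(ii, jj)]

    def total_contacts(self) -> int:
        return int(np.triu(self.entries, k=1).sum())

    def same_window(self, other: "ContactMatrix") -> bool:
        return (self.lo, self.hi) == (other.lo, other.hi)


@dataclass(frozen=True)
class LigandContactVector:
    """Binary per-residue ligand-contact fingerprint L of one structure."""

    structure_id: str
    lo: int
    hi: int
    L: np.ndarray  # (hi - lo + 1,) uint8
    ligand_ref: str = ""

    def __post_init__(self):
        L = np.asarray(self.L, dtype=np.uint8)
        if L.shape != (self.hi - self.lo + 1,):
            raise WindowError("vector length does not match window")
        if L.max(initial=0) > 1:
            raise WindowError("ligand contact vector must be binary")
        object.__setattr__(self, "L", L)

    def contacted_residues(self) -> list[int]:
        return [int(k) + self.lo for k in np.nonzero(self.L)[0]]

    def restrict(self, lo: int, hi: int) -> "LigandContactVector":
        if lo > hi:
            raise WindowError(f"invalid window [{lo}, {hi}]")
        out = np.zeros(hi - lo + 1, dtype=np.uint8)
        src_lo, src_hi = max(lo, self.lo), min(hi, self.hi)
        if src_lo <= src_hi:
            out[src_lo - lo : src_hi - lo + 1] = self.L[src_lo - self.lo : src_hi - self.lo + 1]
        return replace(self, lo=lo, hi=hi, L=out)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Mean contact map of a snapshot ensemble (per-pair contact frequency)."""

    lo: int
    hi: int
    values: np.ndarray  # (n, n) float in [0, 1]
    n_frames: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.hi - self.lo + 1
        if v.shape != (n, n):
            raise WindowError("frequency matrix shape does not match window")
        if not np.allclose(v, v.T):
            raise WindowError("frequency matrix must be symmetric")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise WindowError("frequencies must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def frequency(self, i: int, j: int) -> float:
        return float(self.values[i - self.lo, j - self.lo])

    def same_window(self, other: "FrequencyMatrix") -> bool:
        return (self.lo, self.hi) == (other.lo, other.hi)


def _atom_table(s: Structure, heavy_only: bool) -> tuple[np.ndarray, np.ndarray]:
    coords, labels = [], []
    for idx, atoms in s.residues.items():
        for a in atoms:
            if heavy_only and a.is_hydrogen:
                continue
            coords.append(a.coords)
            labels.append(idx)
    return np.asarray(coords, dtype=float), np.asarray(labels, dtype=int)


def residue_contact_map(
    s: Structure,
    cutoff: float = HEAVY_CUTOFF,
    min_seq_sep: int = MIN_SEQ_SEP,
    window: tuple[int, int] | None = None,
    hydrogen_policy: str = "heavy_only",
) -> ContactMatrix:
    """Binary residue–residue contact map of one structure.

    ``window`` defaults to the span of the structure's resolved residues;
    residues inside the window but unresolved contribute all-zero rows.
    """
    if hydrogen_policy == "heavy_only" and s.has_hydrogens:
        s = strip_hydrogens(s)
    if not s.residues:
        raise EnsembleError(f"{s.id or 'structure'}: no polymer residues")
    coords, labels = _atom_table(s, heavy_only=hydrogen_policy == "heavy_only")
    if window is None:
        window = (min(s.residues), max(s.residues))
    lo, hi = window
    if lo > hi:
        raise WindowError(f"invalid window [{lo}, {hi}]")
    n = hi - lo + 1
    entries = np.zeros((n, n), dtype=np.uint8)

    tree = cKDTree(coords)
    for k, m in tree.query_pairs(r=cutoff):  # closed bound: distance ≤ cutoff
        i, j = int(labels[k]), int(labels[m])
        if abs(i - j) < min_seq_sep:
            continue
        if lo <= i <= hi and lo <= j <= hi:
            entries[i - lo, j - lo] = 1
            entries[j - lo, i - lo] = 1
    return ContactMatrix(
        lo=lo, hi=hi, entries=entries, cutoff=cutoff,
        min_seq_sep=min_seq_sep, hydrogen_policy=hydrogen_policy, structure_id=s.id,
    )


def ligand_contact_vector(
    s: Structure,
    cutoff: float = HEAVY_CUTOFF,
    window: tuple[int, int] | None = None,
    hydrogen_policy: str = "heavy_only",
) -> LigandContactVector:
    """Binary vector L with L_i = 1 iff residue i touches the ligand.

    No sequence-separation rule applies (a ligand has no sequence index).
    Structures without a ligand raise :class:`EnsembleError`; apo entries are
    excluded from all ligand statistics.
    """
    if hydrogen_policy == "heavy_only" and s.has_hydrogens:
        s = strip_hydrogens(s)
    if not s.ligands:
        raise EnsembleError(f"{s.id or 'structure'}: no ligand entity (apo?)")
    if not s.residues:
        raise EnsembleError(f"{s.id or 'structure'}: no polymer residues")
    coords, labels = _atom_table(s, heavy_only=hydrogen_policy == "heavy_only")
    lig_coords = np.asarray(
        [a.coords for lig in s.ligands for a in lig.atoms
         if not (hydrogen_policy == "heavy_only" and a.is_hydrogen)],
        dtype=float,
    )
    if window is None:
        window = (min(s.residues), max(s.residues))
    lo, hi = window
    L = np.zeros(hi - lo + 1, dtype=np.uint8)
    tree = cKDTree(lig_coords)
    dmin, _ = tree.query(coords, k=1)
    for idx, d in zip(labels, dmin):
        if d <= cutoff and lo <= idx <= hi:
            L[int(idx) - lo] = 1
    ref = "+".join(s.ligands[0].component_ids)
    return LigandContactVector(structure_id=s.id, lo=lo, hi=hi, L=L, ligand_ref=ref)


def restrict_window(m: ContactMatrix, lo: int = COMMON_WINDOW[0], hi: int = COMMON_WINDOW[1]) -> ContactMatrix:
    """Re-window a contact map to [lo, hi] (default: the 276–475 common
    region, a 200×200 matrix).  Indices outside the new window are dropped;
    indices inside it but outside the source window become zero rows."""
    if lo > hi:
        raise WindowError(f"invalid window [{lo}, {hi}]")
    n = hi - lo + 1
    entries = np.zeros((n, n), dtype=np.uint8)
    src_lo, src_hi = max(lo, m.lo), min(hi, m.hi)
    if src_lo <= src_hi:
        a, b = src_lo - m.lo, src_hi - m.lo + 1
        c, d = src_lo - lo, src_hi - lo + 1
        entries[c:d, c:d] = m.entries[a:b, a:b]
    return replace(m, lo=lo, hi=hi, entries=entries)


def mean_contact_map(
    frames: Iterable[Structure],
    cutoff: float = ALL_ATOM_CUTOFF,
    hydrogen_policy: str = "all_atom",
    min_seq_sep: int = MIN_SEQ_SEP,
    window: tuple[int, int] | None = None,
) -> FrequencyMatrix:
    """Per-pair contact frequency over a snapshot ensemble.

    Streams over ``frames`` (any iterable, including a lazy generator), so
    arbitrarily long trajectories are processed in bounded memory.
    """
    total: np.ndarray | None = None
    win: tuple[int, int] | None = window
    reference: list[int] | None = None
    n_frames = 0
    for frame in frames:
        if reference is None:
            reference = frame.residue_indices
        elif frame.residue_indices != reference:
            raise EnsembleError(
                f"frame {frame.id or n_frames + 1} does not share the residue list "
                "of the first frame"
            )
        m = residue_contact_map(
            frame, cutoff=cutoff, min_seq_sep=min_seq_sep,
            window=win, hydrogen_policy=hydrogen_policy,
        )
        if win is None:
            win = (m.lo, m.hi)
        if total is None:
            total = np.zeros(m.entries.shape, dtype=np.int64)
        total += m.entries
        n_frames += 1
    if n_frames == 0 or total is None or win is None:
        raise EnsembleError("mean_contact_map requires at least one frame")
    return FrequencyMatrix(lo=win[0], hi=win[1], values=total / n_frames, n_frames=n_frames)


def frequency_from_maps(maps: Iterable[ContactMatrix]) -> FrequencyMatrix:
    """Mean contact frequency of pre-computed binary contact maps."""
    total: np.ndarray | None = None
    win: tuple[int, int] | None = None
    n = 0
    for m in maps:
        if win is None:
            win = (m.lo, m.hi)
            total = np.zeros(m.entries.shape, dtype=np.int64)
        elif (m.lo, m.hi) != win:
            raise EnsembleError("contact maps do not share a window")
        total += m.entries
        n += 1
    if n == 0 or total is None or win is None:
        raise EnsembleError("at least one contact map required")
    return FrequencyMatrix(lo=win[0], hi=win[1], values=total / n, n_frames=n)


# ---------------------------------------------------------------------------
# serialization


def to_sparse_text(m: ContactMatrix) -> str:
    """Upper-triangle (i, j, value) triplets, 1-based author numbering."""
    lines = [f"# window {m.lo} {m.hi} cutoff {m.cutoff} min_seq_sep {m.min_seq_sep}"]
    lines += [f"{i}\t{j}\t1" for i, j in m.contact_pairs()]
    return "\n".join(lines) + "\n"


def from_sparse_text(text: str) -> ContactMatrix:
    header = None
    pairs = []
    for line in text.splitlines():
        if line.startswith("#"):
            header = line.split()
        elif line.strip():
            i, j, v = line.split()
            if int(v):
                pairs.append((int(i), int(j)))
    if header is None:
        raise WindowError("sparse text lacks the window header")
    lo, hi = int(header[2]), int(header[3])
    cutoff, mss = float(header[5]), int(header[7])
    entries = np.zeros((hi - lo + 1, hi - lo + 1), dtype=np.uint8)
    for i, j in pairs:
        entries[i - lo, j - lo] = entries[j - lo, i - lo] = 1
    return ContactMatrix(lo=lo, hi=hi, entries=entries, cutoff=cutoff, min_seq_sep=mss)


def to_dense_csv(m: ContactMatrix | FrequencyMatrix) -> str:
    import pandas as pd

    data = m.entries if isinstance(m, ContactMatrix) else m.values
    idx = list(range(m.lo, m.hi + 1))
    return pd.DataFrame(data, index=idx, columns=idx).to_csv()
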