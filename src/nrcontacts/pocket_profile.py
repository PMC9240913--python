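"""Binding-pocket residues, per-class ligand-contact tallies and the
agonist contact score.

Across an ensemble of ligand-bound structures, each residue i accumulates
N_i^T = N_i^A + N_i^I ligand contacts, split by the activity class of the
structure the contact occurs in.  The agonist contact score

    x_i = (N_i^A − N_i^I) / (N_i^A + N_i^I)  ∈ [−1, +1]

is +1 for residues whose ligand contacts occur only in active structures and
−1 for contacts exclusive to inactive structures.  Residues with too few
contacts overall (N_T ≤ min_total − 1) are filtered from the score to avoid
poor statistics; residues contacted in at least ``min_hits`` structures
define the binding pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contacts import LigandContactVector
from .errors import EnsembleError, WindowError
from .structure_io import Structure

POCKET_MIN_HITS = 10
SCORE_MIN_TOTAL = 10
HOTSPOT_THRESHOLD = -0.5


@dataclass(frozen=True)
class PocketProfile:
    """Per-residue ligand-contact statistics over an ensemble."""

    residue_indices: np.ndarray  # (n,) int
    n_total: np.ndarray  # (n,) int, N_T
    n_active: np.ndarray  # (n,) int, N_A
    n_inactive: np.ndarray  # (n,) int, N_I
    x: np.ndarray | None = None  # (n,) float, NaN where filtered
    x_filtered: np.ndarray | None = None  # (n,) bool
    is_pocket: np.ndarray | None = None  # (n,) bool
    min_total_used: int | None = None
    min_hits_used: int | None = None

    def __post_init__(self):
        if not np.array_equal(self.n_total, self.n_active + self.n_inactive):
            raise EnsembleError("N_T must equal N_A + N_I")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "residue_index": self.residue_indices,
                "N_T": self.n_total,
                "N_A": self.n_active,
                "N_I": self.n_inactive,
            }
        )
        if self.x is not None:
            df["x"] = self.x
            df["filtered"] = self.x_filtered
        if self.is_pocket is not None:
            df["is_pocket"] = self.is_pocket
        return df

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.4f")


def _stack(vectors: list[LigandContactVector]) -> tuple[np.ndarray, np.ndarray]:
    if not vectors:
        raise EnsembleError("at least one ligand-contact vector required")
    lo, hi = vectors[0].lo, vectors[0].hi
    for v in vectors[1:]:
        if (v.lo, v.hi) != (lo, hi):
            raise WindowError("ligand-contact vectors do not share a window")
    idx = np.arange(lo, hi + 1)
    X = np.stack([v.L for v in vectors]).astype(np.int64)
    return idx, X


def pocket_residues(
    vectors: list[LigandContactVector], min_hits: int = POCKET_MIN_HITS
) -> set[int]:
    """Residues contacting a ligand in at least ``min_hits`` structures."""
    idx, X = _stack(vectors)
    hits = X.sum(axis=0)
    return {int(i) for i, h in zip(idx, hits) if h >= min_hits}


def contact_counts_by_class(
    vectors: list[LigandContactVector], labels: dict[str, str]
) -> PocketProfile:
    """Per-residue N_T / N_A / N_I as restricted sums over the activity
    classes.  Every vector's structure must appear in ``labels`` with value
    ACTIVE or INACTIVE."""
    idx, X = _stack(vectors)
    lab = []
    for v in vectors:
        if v.structure_id not in labels:
            raise EnsembleError(f"structure {v.structure_id!r} has no activity label")
        l = labels[v.structure_id].upper()
        if l not in ("ACTIVE", "INACTIVE"):
            raise EnsembleError(f"label {l!r} for {v.structure_id!r} is not ACTIVE/INACTIVE")
        lab.append(l)
    active = np.array([l == "ACTIVE" for l in lab])
    n_a = X[active].sum(axis=0) if active.any() else np.zeros(X.shape[1], dtype=np.int64)
    n_i = X[~active].sum(axis=0) if (~active).any() else np.zeros(X.shape[1], dtype=np.int64)
    return PocketProfile(
        residue_indices=idx, n_total=n_a + n_i, n_active=n_a, n_inactive=n_i
    )


def agonist_score(p: PocketProfile, min_total: int = SCORE_MIN_TOTAL) -> PocketProfile:
    """Attach the agonist contact score x = (N_A − N_I)/(N_A + N_I),
    filtering residues with N_T < min_total (reported as NaN + filtered)."""
    filtered = p.n_total < min_total
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (p.n_active - p.n_inactive) / p.n_total.astype(float)
    x = np.where(filtered, np.nan, x)
    return replace(p, x=x, x_filtered=filtered, min_total_used=min_total)


def mark_pocket(p: PocketProfile, min_hits: int = POCKET_MIN_HITS) -> PocketProfile:
    """Flag pocket residues (N_T ≥ min_hits) on the profile."""
    return replace(p, is_pocket=p.n_total >= min_hits, min_hits_used=min_hits)


def hot_spots(p: PocketProfile, threshold: float = HOTSPOT_THRESHOLD) -> list[int]:
    """Inverse-agonist hot spots: scored residues with x below ``threshold``."""
    if p.x is None:
        raise EnsembleError("profile has no score: call agonist_score first")
    return [
        int(i)
        for i, xv in zip(p.residue_indices, p.x)
        if not np.isnan(xv) and xv < threshold
    ]


@dataclass(frozen=True)
class LigandSizeStats:
    n_mean: float
    n_sd: float
    n_active_mean: float | None
    n_inactive_mean: float | None
    definition: str
    n_structures: int


def ligand_size(s: Structure, definition: str = "heavy_atoms") -> float:
    if not s.ligands:
        raise EnsembleError(f"{s.id or 'structure'}: no ligand")
    if definition == "heavy_atoms":
        return float(sum(l.n_atoms_heavy for l in s.ligands))
    if definition == "total_atoms":
        return float(sum(l.n_atoms_total for l in s.ligands))
    if definition == "molecular_weight":
        return float(sum(l.molecular_weight for l in s.ligands))
    raise ValueError(f"unknown ligand-size definition {definition!r}")


def ligand_size_stats(
    structures: list[Structure],
    labels: dict[str, str],
    definition: str = "heavy_atoms",
    ddof: int = 0,
) -> LigandSizeStats:
    """Mean/SD of ligand size overall and per activity class.

    The spread is descriptive, so the population SD (ddof=0) is the default.
    An empty class yields None for that class mean.
    """
    sizes = np.array([ligand_size(s, definition) for s in structures])
    lab = np.array([labels[s.id].upper() for s in structures])
    act, inact = sizes[lab == "ACTIVE"], sizes[lab == "INACTIVE"]
    return LigandSizeStats(
        n_mean=float(sizes.mean()),
        n_sd=float(sizes.std(ddof=ddof)),
        n_active_mean=float(act.mean()) if act.size else None,
        n_inactive_mean=float(inact.mean()) if inact.size else None,
        definition=definition,
        n_structures=len(structures),
    )
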