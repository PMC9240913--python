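"""Conserved high-frequency contacts within and across receptors.

A contact is conserved between two ensembles (apo vs holo of one receptor)
when its frequency exceeds the threshold — strictly greater than 50% by
default — in both.  Comparison across receptors routes the contact pairs
through a global sequence alignment of the two LBDs, keeping only pairs
whose both residues align onto non-gap positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .contacts import FrequencyMatrix
from .errors import EnsembleError, WindowError

CONSERVATION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConservedContactSet:
    """Contact pairs (receptor-1 numbering) above threshold in all required
    ensembles, with their per-ensemble frequencies."""

    pairs: tuple[tuple[int, int], ...]
    f1: tuple[float, ...]
    f2: tuple[float, ...]
    threshold: float
    mapped_pairs: tuple[tuple[int, int], ...] | None = None  # receptor-2 numbering

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self) -> str:
        header = "i1\tj1\ti2\tj2\tf1\tf2\tconserved"
        lines = [header]
        mp = self.mapped_pairs or tuple((i, j) for i, j in self.pairs)
        for (i1, j1), (i2, j2), a, b in zip(self.pairs, mp, self.f1, self.f2):
            lines.append(f"{i1}\t{j1}\t{i2}\t{j2}\t{a:.4f}\t{b:.4f}\t1")
        return "\n".join(lines) + "\n"


def _support(f: FrequencyMatrix, threshold: float) -> set[tuple[int, int]]:
    ii, jj = np.nonzero(np.triu(f.values > threshold, k=1))
    return {(int(i) + f.lo, int(j) + f.lo) for i, j in zip(ii, jj)}


def conserved_within(
    f1: FrequencyMatrix, f2: FrequencyMatrix, threshold: float = CONSERVATION_THRESHOLD
) -> ConservedContactSet:
    """Pairs with frequency strictly above ``threshold`` in both ensembles
    (a frequency of exactly 0.5 does not qualify at the default)."""
    if not f1.same_window(f2):
        raise WindowError("frequency matrices do not share a window")
    pairs = sorted(_support(f1, threshold) & _support(f2, threshold))
    return ConservedContactSet(
        pairs=tuple(pairs),
        f1=tuple(f1.frequency(i, j) for i, j in pairs),
        f2=tuple(f2.frequency(i, j) for i, j in pairs),
        threshold=threshold,
    )


@dataclass(frozen=True)
class AlignmentMap:
    """One-to-one residue correspondence from a global pairwise alignment."""

    pairs: tuple[tuple[int, int], ...]  # (receptor1_index, receptor2_index)
    identity_count: int
    score: float
    params: dict

    def __post_init__(self):
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise EnsembleError("alignment map is not one-to-one")

    @property
    def forward(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def backward(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}

    def invert(self) -> "AlignmentMap":
        return AlignmentMap(
            pairs=tuple((b, a) for a, b in self.pairs),
            identity_count=self.identity_count,
            score=self.score,
            params=self.params,
        )


def align_sequences(
    seq1: str,
    seq2: str,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    start1: int = 1,
    start2: int = 1,
) -> AlignmentMap:
    """Global (Needleman–Wunsch) alignment of two amino-acid sequences.

    Defaults: BLOSUM62 with affine gap penalties 10 (open) / 0.5 (extend).
    Pass ``matrix=None`` for simple match/mismatch scoring (used by the
    exhaustive-enumeration cross-checks on short sequences).  ``start1`` and
    ``start2`` anchor the author numbering of the first residue of each
    sequence (e.g. 265 for an LBD construct starting at A265).
    """
    if not seq1 or not seq2:
        raise EnsembleError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq1.upper(), seq2.upper())[0]
    pairs = []
    identity = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for k in range(e1 - s1):
            a, b = s1 + k, s2 + k
            pairs.append((a + start1, b + start2))
            if seq1[a].upper() == seq2[b].upper():
                identity += 1
    return AlignmentMap(
        pairs=tuple(pairs),
        identity_count=identity,
        score=float(aln.score),
        params={
            "matrix": matrix, "match": match, "mismatch": mismatch,
            "gap_open": gap_open, "gap_extend": gap_extend, "mode": "global",
        },
    )


def map_contacts(
    pairs: list[tuple[int, int]], amap: AlignmentMap
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Carry contact pairs into the partner receptor's numbering.

    Returns (mapped pairs in receptor-2 numbering, pairs dropped because at
    least one residue faces a gap)."""
    fwd = amap.forward
    mapped, unmapped = [], []
    for i, j in pairs:
        if i in fwd and j in fwd:
            a, b = fwd[i], fwd[j]
            mapped.append((min(a, b), max(a, b)))
        else:
            unmapped.append((i, j))
    return mapped, unmapped


def cross_receptor_conserved(
    fA: FrequencyMatrix,
    fB: FrequencyMatrix,
    amap: AlignmentMap,
    threshold: float = CONSERVATION_THRESHOLD,
) -> ConservedContactSet:
    """Contacts above threshold in receptor A's ensemble whose aligned
    counterparts are also above threshold in receptor B's ensemble."""
    fwd = amap.forward
    keep, mapped, a_freq, b_freq = [], [], [], []
    for i, j in sorted(_support(fA, threshold)):
        if i not in fwd or j not in fwd:
            continue
        a, b = fwd[i], fwd[j]
        a, b = min(a, b), max(a, b)
        if not (fB.lo <= a and b <= fB.hi):
            continue
        if fB.frequency(a, b) > threshold:
            keep.append((i, j))
            mapped.append((a, b))
            a_freq.append(fA.frequency(i, j))
            b_freq.append(fB.frequency(a, b))
    return ConservedContactSet(
        pairs=tuple(keep),
        f1=tuple(a_freq),
        f2=tuple(b_freq),
        threshold=threshold,
        mapped_pairs=tuple(mapped),
    )


def frequency_scatter_table(
    fA: FrequencyMatrix,
    fB: FrequencyMatrix,
    amap: AlignmentMap | None = None,
    threshold: float = CONSERVATION_THRESHOLD,
):
    """All common pairs with both frequencies and a conserved flag — the
    tabular counterpart of a paired-frequency scatter plot."""
    import pandas as pd

    rows = []
    if amap is None:
        if not fA.same_window(fB):
            raise WindowError("frequency matrices do not share a window")
        n = fA.hi - fA.lo + 1
        for i in range(n):
            for j in range(i + 1, n):
                a, b = float(fA.values[i, j]), float(fB.values[i, j])
                if a > 0 or b > 0:
                    rows.append((i + fA.lo, j + fA.lo, i + fA.lo, j + fA.lo, a, b,
                                 int(a > threshold and b > threshold)))
    else:
        fwd = amap.forward
        for i in range(fA.lo, fA.hi + 1):
            for j in range(i + 1, fA.hi + 1):
                if i not in fwd or j not in fwd:
                    continue
                a2, b2 = sorted((fwd[i], fwd[j]))
                if not (fB.lo <= a2 and b2 <= fB.hi):
                    continue
                a, b = fA.frequency(i, j), fB.frequency(a2, b2)
                if a > 0 or b > 0:
                    rows.append((i, j, a2, b2, a, b, int(a > threshold and b > threshold)))
    return pd.DataFrame(rows, columns=["i1", "j1", "i2", "j2", "f1", "f2", "conserved"])
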