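"""Synthetic fixtures with the statistical structure each pipeline stage
assumes.

Four generators stand in for the data a study of this kind consumes:

* coordinate fixtures — toy structures with single-atom residues placed at
  exact pairwise distances, for exercising the geometric contact definition;
* two-state contact-map ensembles — active/inactive conformer populations
  that differ in the fill of the two C-terminal activity regions on top of a
  shared background, for classifier and clustering tests;
* binding-mode fingerprint ensembles — residue–ligand contact vectors drawn
  from two disjoint-support prototypes (canonical vs allosteric pocket)
  with independent flip noise, for interaction-PCA tests;
* Bernoulli snapshot ensembles — frame lists drawn from a prescribed
  contact-frequency matrix, for trajectory-statistics tests.

Each generator owns one RNG stream seeded explicitly, so every fixture is
bit-reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity_classifier import ACTIVITY_CUTOFF, REGION1, REGION2, _in_region1, _in_region2
from .contacts import ContactMatrix, FrequencyMatrix, LigandContactVector, MIN_SEQ_SEP
from .errors import GeometryError, EnsembleError
from .structure_io import AtomRecord, LigandEntity, Structure


# ---------------------------------------------------------------------------
# coordinate fixtures


def make_coordinate_fixture(
    pairs: list[tuple[int, int, float]],
    structure_id: str = "fixture",
    min_far: float = 20.0,
) -> Structure:
    """Structure of single-atom residues with listed pairs at exact distances.

    Residues appearing in ``pairs`` are embedded so each listed pair sits at
    exactly the requested distance while every unlisted pair within the
    fixture is at least ``min_far`` Å apart.  Disconnected groups of
    constraints are placed on a coarse grid far from each other.  Requests
    whose geometry cannot satisfy the far-apart guarantee (e.g. two short
    edges sharing a residue) raise :class:`GeometryError`.
    """
    if any(d <= 0 for _, _, d in pairs):
        raise GeometryError("pair distances must be positive")
    edges: dict[int, list[tuple[int, float]]] = {}
    listed = set()
    for i, j, d in pairs:
        if i == j:
            raise GeometryError(f"self-pair ({i},{i}) is not a distance constraint")
        edges.setdefault(i, []).append((j, d))
        edges.setdefault(j, []).append((i, d))
        listed.add((min(i, j), max(i, j)))

    # connected components of the constraint graph
    components: list[list[int]] = []
    seen: set[int] = set()
    for start in sorted(edges):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(v for v, _ in edges[u] if v not in seen)
        components.append(sorted(comp))

    # orthogonal-ish directions for greedy tree embedding
    dirs = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
        dtype=float,
    )
    placed: dict[int, np.ndarray] = {}
    spacing = 1000.0
    for c, comp in enumerate(components):
        base = np.array([c * spacing, 0.0, 0.0])
        root = comp[0]
        placed[root] = base
        queue = [root]
        visited = {root}
        while queue:
            u = queue.pop(0)
            for k, (v, d) in enumerate(sorted(edges[u])):
                if v in visited:
                    continue
                placed[v] = placed[u] + dirs[k % len(dirs)] * d
                visited.add(v)
                queue.append(v)

    # verify every constraint exactly, and the far-apart guarantee
    for i, j, d in pairs:
        got = float(np.linalg.norm(placed[i] - placed[j]))
        if abs(got - d) > 1e-9:
            raise GeometryError(
                f"inconsistent constraints: pair ({i},{j}) realised at {got:.3f} Å, "
                f"requested {d:.3f} Å"
            )
    residues = sorted(placed)
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            i, j = residues[a], residues[b]
            if (i, j) in listed:
                continue
            if float(np.linalg.norm(placed[i] - placed[j])) < min_far:
                raise GeometryError(
                    f"unlisted pair ({i},{j}) cannot be kept ≥ {min_far} Å apart "
                    "under the requested constraints"
                )

    res = {
        i: (
            AtomRecord(
                name="CA", element="C", coords=placed[i], residue_index=i,
                residue_name="GLY", chain_id="A", record_class="polymer",
                is_hydrogen=False,
            ),
        )
        for i in residues
    }
    return Structure(id=structure_id, residues=res, ligands=())


def add_ligand(
    s: Structure, position: np.ndarray, n_atoms: int = 1, component_id: str = "LIG"
) -> Structure:
    """Attach a point-cloud ligand (atoms within 0.5 Å of ``position``)."""
    position = np.asarray(position, dtype=float)
    atoms = tuple(
        AtomRecord(
            name=f"C{k + 1}", element="C",
            coords=position + np.array([0.0, 0.0, 0.4 * k / max(n_atoms - 1, 1)]),
            residue_index=900, residue_name=component_id, chain_id="A",
            record_class="hetero", is_hydrogen=False,
        )
        for k in range(n_atoms)
    )
    from dataclasses import replace

    return replace(s, ligands=s.ligands + (LigandEntity((component_id,), atoms),))


# ---------------------------------------------------------------------------
# two-state contact-map ensembles


@dataclass(frozen=True)
class TwoStateSpec:
    """Study conditions for the active/inactive contact-map generator."""

    n_active: int = 10
    n_inactive: int = 10
    window: tuple[int, int] = (265, 507)
    active_fill: int = 70  # region contacts per active structure (≥ cutoff)
    inactive_fill: int = 20  # region contacts per inactive structure
    background_density: float = 0.05
    noise_swaps: int = 3  # count-preserving region-contact swaps per structure
    cutoff: int = ACTIVITY_CUTOFF
    margin: int = 10
    seed: int = 0


def region_candidate_pairs(window: tuple[int, int], min_seq_sep: int) -> list[tuple[int, int]]:
    lo, hi = window
    out = []
    for i in range(lo, hi + 1):
        for j in range(i + min_seq_sep, hi + 1):
            if _in_region1(i, j) or _in_region2(i, j):
                out.append((i, j))
    return out


def background_candidate_pairs(window: tuple[int, int], min_seq_sep: int) -> list[tuple[int, int]]:
    lo, hi = window
    out = []
    for i in range(lo, hi + 1):
        for j in range(i + min_seq_sep, hi + 1):
            if not (_in_region1(i, j) or _in_region2(i, j)):
                out.append((i, j))
    return out


def contact_matrix_from_pairs(
    pairs: set[tuple[int, int]], window: tuple[int, int], structure_id: str
) -> ContactMatrix:
    lo, hi = window
    n = hi - lo + 1
    entries = np.zeros((n, n), dtype=np.uint8)
    for i, j in pairs:
        entries[i - lo, j - lo] = entries[j - lo, i - lo] = 1
    return ContactMatrix(
        lo=lo, hi=hi, entries=entries, cutoff=4.5,
        min_seq_sep=MIN_SEQ_SEP, hydrogen_policy="heavy_only", structure_id=structure_id,
    )


def make_two_state_ensemble(spec: TwoStateSpec) -> tuple[list[ContactMatrix], list[str]]:
    """Labeled contact-map ensemble with two planted conformational states.

    Each class has a prototype set of activity-region contacts (fill counts
    straddle the classifier cutoff by at least ``margin``); members perturb
    the prototype by count-preserving swaps, and all structures share one
    random non-region background, so clustering has to separate the classes
    on the planted region signal.
    """
    if spec.margin <= 0:
        raise EnsembleError("margin must be positive")
    if spec.active_fill < spec.cutoff:
        raise EnsembleError("active_fill must reach the activity cutoff")
    if spec.inactive_fill > spec.cutoff - spec.margin:
        raise EnsembleError("inactive_fill must stay at or below cutoff − margin")
    rng = np.random.default_rng(spec.seed)
    region = region_candidate_pairs(spec.window, MIN_SEQ_SEP)
    if spec.active_fill > len(region):
        raise EnsembleError("active_fill exceeds the number of region pairs")
    background = background_candidate_pairs(spec.window, MIN_SEQ_SEP)
    n_bg = int(round(spec.background_density * len(background)))
    bg_idx = rng.choice(len(background), size=n_bg, replace=False)
    shared_bg = {background[k] for k in bg_idx}

    def prototype(fill: int) -> list[tuple[int, int]]:
        idx = rng.choice(len(region), size=fill, replace=False)
        return [region[k] for k in idx]

    proto = {"ACTIVE": prototype(spec.active_fill), "INACTIVE": prototype(spec.inactive_fill)}

    maps, labels = [], []
    counts = [("ACTIVE", spec.n_active), ("INACTIVE", spec.n_inactive)]
    serial = 0
    for label, n in counts:
        for _ in range(n):
            member = set(proto[label])
            absent = [p for p in region if p not in member]
            k = min(spec.noise_swaps, len(member), len(absent))
            if k > 0:
                drop = rng.choice(len(member), size=k, replace=False)
                add = rng.choice(len(absent), size=k, replace=False)
                member_list = sorted(member)
                for a, b in zip(drop, add):
                    member.discard(member_list[a])
                    member.add(absent[b])
            serial += 1
            maps.append(
                contact_matrix_from_pairs(member | shared_bg, spec.window, f"syn{serial:03d}")
            )
            labels.append(label)
    return maps, labels


# ---------------------------------------------------------------------------
# binding-mode fingerprint ensembles


@dataclass(frozen=True)
class BindingModeSpec:
    """Conditions for the canonical/allosteric fingerprint generator."""

    n_canonical: int = 50
    n_allosteric: int = 50
    window: tuple[int, int] = (276, 325)
    support_size: int = 12  # residues contacted by each prototype
    flip_prob: float = 0.05
    seed: int = 0


def make_binding_mode_ensemble(
    spec: BindingModeSpec,
) -> tuple[list[LigandContactVector], list[str]]:
    """Labeled ligand-contact vectors from two disjoint-support prototypes.

    Each sample is its mode's prototype with independent per-residue flips
    at rate ε = ``flip_prob``; ε ≥ 0.5 would destroy the mode signal and is
    rejected."""
    if not 0 <= spec.flip_prob < 0.5:
        raise EnsembleError("flip probability must satisfy 0 ≤ ε < 0.5")
    lo, hi = spec.window
    n = hi - lo + 1
    if 2 * spec.support_size > n:
        raise EnsembleError("prototype supports must fit disjointly in the window")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    proto = {
        "canonical": np.zeros(n, dtype=np.uint8),
        "allosteric": np.zeros(n, dtype=np.uint8),
    }
    proto["canonical"][perm[: spec.support_size]] = 1
    proto["allosteric"][perm[spec.support_size : 2 * spec.support_size]] = 1

    vectors, labels = [], []
    serial = 0
    for mode, count in (("canonical", spec.n_canonical), ("allosteric", spec.n_allosteric)):
        for _ in range(count):
            flips = rng.random(n) < spec.flip_prob
            L = proto[mode] ^ flips.astype(np.uint8)
            serial += 1
            vectors.append(
                LigandContactVector(
                    structure_id=f"lig{serial:03d}", lo=lo, hi=hi, L=L, ligand_ref=mode
                )
            )
            labels.append(mode)
    return vectors, labels


# ---------------------------------------------------------------------------
# Bernoulli snapshot ensembles


def make_frequency_matrix(
    window: tuple[int, int],
    base: float = 0.0,
    planted: list[tuple[int, int, float]] | None = None,
    min_seq_sep: int = MIN_SEQ_SEP,
) -> FrequencyMatrix:
    """Frequency matrix with a uniform base rate plus planted pair rates."""
    lo, hi = window
    n = hi - lo + 1
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            v[i, j] = v[j, i] = base
    for i, j, p in planted or []:
        v[i - lo, j - lo] = v[j - lo, i - lo] = p
    return FrequencyMatrix(lo=lo, hi=hi, values=v, n_frames=0)


def make_bernoulli_trajectory(
    P: FrequencyMatrix, n_frames: int, seed: int
) -> list[ContactMatrix]:
    """Frames whose contact (i, j) forms independently with probability P_ij."""
    rng = np.random.default_rng(seed)
    n = P.hi - P.lo + 1
    iu = np.triu_indices(n, k=1)
    probs = P.values[iu]
    frames = []
    for f in range(n_frames):
        draws = (rng.random(probs.shape) < probs).astype(np.uint8)
        entries = np.zeros((n, n), dtype=np.uint8)
        entries[iu] = draws
        entries += entries.T
        frames.append(
            ContactMatrix(
                lo=P.lo, hi=P.hi, entries=entries, cutoff=4.2,
                min_seq_sep=1, hydrogen_policy="all_atom",
                structure_id=f"frame{f + 1:06d}",
            )
        )
    return frames
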