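"""Read protein–ligand complexes from PDB text into a uniform heavy-atom model.

The model deliberately keeps only what the contact analysis needs: author
residue numbering of a single polymer chain, heavy-atom coordinates, and the
hetero components bound to that chain pooled into one ligand entity per
structure.  Alternate locations are resolved to the highest-occupancy
conformer; insertion codes are rejected rather than silently renumbered,
because all downstream statistics are keyed on integer residue indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EnsembleError, NumberingError, ParseError

#: Hetero components treated as solvent/buffer, never as ligand.
DEFAULT_EXCLUDED_COMPONENTS = frozenset(
    {"HOH", "DOD", "WAT", "NA", "CL", "K", "MG", "ZN", "CA", "SO4", "PO4",
     "GOL", "EDO", "PEG", "PG4", "ACT", "DMS", "FMT", "MPD", "TRS"}
)

#: Monoisotopic-ish standard atomic weights for ligand-size statistics (g/mol).
ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "B": 10.81, "SE": 78.971, "SI": 28.085,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in author numbering."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    residue_index: int
    residue_name: str
    chain_id: str
    record_class: str  # "polymer" | "hetero"
    is_hydrogen: bool

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ParseError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class LigandEntity:
    """All non-solvent hetero components of one structure, pooled.

    Several crystal entries carry multiple hetero fragments in one pocket
    (fragment cocktails); those are treated as a single ligand, so
    ``component_ids`` may list more than one chemical-component code.
    """

    component_ids: tuple[str, ...]
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ParseError("ligand entity with no atoms")

    @property
    def n_atoms_total(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms_heavy(self) -> int:
        return sum(not a.is_hydrogen for a in self.atoms)

    @property
    def molecular_weight(self) -> float:
        return float(sum(ATOMIC_MASS.get(a.element.upper(), 0.0) for a in self.atoms))


@dataclass(frozen=True)
class Structure:
    """A single-chain protein (residue-indexed atom lists) plus its ligand."""

    id: str
    residues: dict[int, tuple[AtomRecord, ...]]
    ligands: tuple[LigandEntity, ...]
    numbering_scheme: str = "OTHER"  # RORG | RORGT | INTERNAL | OTHER
    numbering_offset: int = 0

    def __post_init__(self):
        idx = list(self.residues)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise NumberingError(f"{self.id}: residue indices not strictly increasing")

    @property
    def residue_indices(self) -> list[int]:
        return list(self.residues)

    def atoms(self, heavy_only: bool = False) -> Iterator[AtomRecord]:
        for atoms in self.residues.values():
            for a in atoms:
                if not (heavy_only and a.is_hydrogen):
                    yield a

    @property
    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms()) or any(
            a.is_hydrogen for lig in self.ligands for a in lig.atoms
        )


def _format_pdb_failure(pdb_text: str, exc: Exception) -> str:
    """Best-effort identification of the offending line for error messages."""
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return f"malformed record at line {ln}: {line.rstrip()!r}"
    return f"unparseable PDB text ({exc})"


def _resolve_altloc(arr: struc.AtomArray) -> struc.AtomArray:
    """Keep one conformer per (residue, atom name): highest occupancy,
    ties broken by the alphabetically first altloc identifier."""
    alt = arr.get_annotation("altloc_id")
    occ = arr.get_annotation("occupancy")
    keep = np.ones(arr.array_length(), dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for k in range(arr.array_length()):
        key = (arr.chain_id[k], int(arr.res_id[k]), arr.res_name[k], arr.atom_name[k])
        groups.setdefault(key, []).append(k)
    for idxs in groups.values():
        if len(idxs) > 1:
            best = min(idxs, key=lambda k: (-occ[k], alt[k]))
            for k in idxs:
                keep[k] = k == best
    return arr[keep]


def read_structure(
    pdb_text: str,
    chain: str | None = None,
    structure_id: str = "",
    exclude_components: frozenset[str] | set[str] = DEFAULT_EXCLUDED_COMPONENTS,
    model: int = 1,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    The polymer residues of the selected chain (first polymer chain when
    ``chain`` is None) are kept, together with every hetero component of that
    chain that is not in ``exclude_components``; those components are pooled
    into a single :class:`LigandEntity`.  Waters and configured buffer/ion
    codes are dropped.  Insertion codes or duplicate residue indices raise
    :class:`NumberingError`.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=model, altloc="all", extra_fields=["occupancy"])
    except ParseError:
        raise
    except Exception as exc:  # biotite raises assorted ValueError subclasses
        raise ParseError(_format_pdb_failure(pdb_text, exc)) from exc
    if arr.array_length() == 0:
        raise ParseError("PDB text contains no atom records")

    ins = arr.get_annotation("ins_code")
    if np.any(ins != ""):
        bad = int(np.argmax(ins != ""))
        raise NumberingError(
            f"insertion code {ins[bad]!r} at residue {int(arr.res_id[bad])} "
            f"(chain {arr.chain_id[bad]}): renumber the entry before analysis"
        )

    arr = _resolve_altloc(arr)

    polymer_chains = [c for c in dict.fromkeys(arr.chain_id) if np.any((arr.chain_id == c) & ~arr.hetero)]
    if chain is None:
        if not polymer_chains:
            raise ParseError("no polymer chain in PDB text")
        chain = polymer_chains[0]
    elif chain not in polymer_chains:
        raise ParseError(f"chain {chain!r} has no polymer residues")

    sel = arr[arr.chain_id == chain]

    def record(k, record_class):
        elem = sel.element[k].strip().upper()
        return AtomRecord(
            name=sel.atom_name[k],
            element=sel.element[k],
            coords=sel.coord[k],
            residue_index=int(sel.res_id[k]),
            residue_name=sel.res_name[k],
            chain_id=chain,
            record_class=record_class,
            is_hydrogen=elem in ("H", "D"),
        )

    residues: dict[int, list[AtomRecord]] = {}
    seen_name: dict[int, str] = {}
    lig_atoms: list[AtomRecord] = []
    lig_components: list[str] = []
    for k in range(sel.array_length()):
        if sel.hetero[k]:
            if sel.res_name[k] in exclude_components:
                continue
            lig_atoms.append(record(k, "hetero"))
            if sel.res_name[k] not in lig_components:
                lig_components.append(sel.res_name[k])
        else:
            ridx = int(sel.res_id[k])
            prev = seen_name.setdefault(ridx, sel.res_name[k])
            if prev != sel.res_name[k]:
                raise NumberingError(
                    f"duplicate residue index {ridx} ({prev}/{sel.res_name[k]}) after altLoc resolution"
                )
            residues.setdefault(ridx, []).append(record(k, "polymer"))

    ligands = ()
    if lig_atoms:
        ligands = (LigandEntity(tuple(lig_components), tuple(lig_atoms)),)
    ordered = {i: tuple(residues[i]) for i in sorted(residues)}
    return Structure(id=structure_id, residues=ordered, ligands=ligands)


def strip_hydrogens(s: Structure) -> Structure:
    """Drop hydrogen/deuterium atoms everywhere; idempotent."""
    residues = {
        i: tuple(a for a in atoms if not a.is_hydrogen) for i, atoms in s.residues.items()
    }
    residues = {i: atoms for i, atoms in residues.items() if atoms}
    ligands = tuple(
        LigandEntity(l.component_ids, tuple(a for a in l.atoms if not a.is_hydrogen))
        for l in s.ligands
        if any(not a.is_hydrogen for a in l.atoms)
    )
    return replace(s, residues=residues, ligands=ligands)


def renumber(s: Structure, offset: int, numbering_scheme: str | None = None) -> Structure:
    """Shift every residue index by ``offset``.

    Typical uses: internal 1-based simulation numbering + 264 gives the
    canonical RORγ (UniProt P51449) indices, and RORγt-numbered entries + 21
    map onto RORγ numbering (the t-isoform is 21 residues shorter at the
    N-terminus).
    """
    if offset == 0 and numbering_scheme is None:
        return s

    def shift(a: AtomRecord) -> AtomRecord:
        return replace(a, residue_index=a.residue_index + offset)

    residues = {i + offset: tuple(shift(a) for a in atoms) for i, atoms in s.residues.items()}
    ligands = tuple(
        LigandEntity(l.component_ids, tuple(shift(a) for a in l.atoms)) for l in s.ligands
    )
    return replace(
        s,
        residues=residues,
        ligands=ligands,
        numbering_offset=s.numbering_offset + offset,
        numbering_scheme=numbering_scheme or s.numbering_scheme,
    )


def write_structure(s: Structure) -> str:
    """Serialize a :class:`Structure` back to PDB text (supported subset)."""
    atoms = list(s.atoms()) + [a for lig in s.ligands for a in lig.atoms]
    arr = struc.AtomArray(len(atoms))
    for k, a in enumerate(atoms):
        arr.coord[k] = a.coords
        arr.chain_id[k] = a.chain_id or "A"
        arr.res_id[k] = a.residue_index
        arr.res_name[k] = a.residue_name
        arr.atom_name[k] = a.name
        arr.element[k] = a.element
        arr.hetero[k] = a.record_class == "hetero"
    pdb = PDBFile()
    pdb.set_structure(arr)
    return "\n".join(pdb.lines) + "\n"


def read_snapshot_ensemble(
    source: str,
    topology: str | None = None,
    chain: str | None = None,
    exclude_components: frozenset[str] | set[str] = DEFAULT_EXCLUDED_COMPONENTS,
) -> Iterator[Structure]:
    """Stream the frames of a snapshot ensemble as :class:`Structure` objects.

    ``source`` is either multi-model PDB text (or a path to one) or a
    trajectory file (DCD/XTC/...) with ``topology`` a PDB topology path; the
    trajectory path requires the optional :mod:`mdtraj` dependency.
    Hydrogens are retained — simulation-derived contact analysis is all-atom.
    Frames are yielded lazily so very long trajectories never need to reside
    in memory at once.
    """
    if topology is None:
        text = source
        if "\n" not in source:
            with open(source) as fh:
                text = fh.read()
        try:
            pdb = PDBFile.read(io.StringIO(text))
            n_models = pdb.get_model_count()
        except Exception as exc:
            raise ParseError(_format_pdb_failure(text, exc)) from exc
        reference: list[int] | None = None
        for m in range(1, n_models + 1):
            frame = read_structure(
                text, chain=chain, structure_id=f"frame{m:06d}",
                exclude_components=exclude_components, model=m,
            )
            if reference is None:
                reference = frame.residue_indices
            elif frame.residue_indices != reference:
                raise EnsembleError(f"model {m} residue list differs from model 1")
            yield frame
        return

    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading trajectory files requires the optional 'mdtraj' dependency "
            "(pip install nrcontacts[trajectory])"
        ) from exc
    top_structure = read_structure(
        open(topology).read(), chain=chain, exclude_components=exclude_components
    )
    top = mdtraj.load_topology(topology)
    for chunk in mdtraj.iterload(source, top=top, chunk=100):
        for f in range(chunk.n_frames):
            coords = np.asarray(chunk.xyz[f], dtype=float) * 10.0  # nm → Å
            yield _with_coords(top_structure, top, coords)


def _with_coords(template: Structure, top, coords: np.ndarray) -> Structure:
    if top.n_atoms != coords.shape[0]:
        raise EnsembleError("frame/topology atom-count mismatch")
    new_res: dict[int, tuple[AtomRecord, ...]] = {}
    by_key = {
        (a.residue_index, a.name): a for atoms in template.residues.values() for a in atoms
    }
    updated: dict[int, list[AtomRecord]] = {i: [] for i in template.residues}
    for atom, xyz in zip(top.atoms, coords):
        key = (atom.residue.resSeq, atom.name)
        rec = by_key.get(key)
        if rec is not None:
            updated[rec.residue_index].append(replace(rec, coords=xyz))
    for i, atoms in updated.items():
        new_res[i] = tuple(atoms)
    return replace(template, residues=new_res)
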