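"""End-to-end orchestration: structures in, tables and trees out.

``run_pipeline`` executes the crystal-ensemble analysis — contact maps,
activity calls, dissimilarity clustering, pocket profile, agonist scores and
interaction PCA — and writes every table plus a manifest recording all
thresholds in force.  Each stage failure is re-raised with the stage name so
batch runs point at the guilty step.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import (
    ACTIVITY_CUTOFF,
    ALL_ATOM_CUTOFF,
    COMMON_WINDOW,
    HEAVY_CUTOFF,
    MIN_SEQ_SEP,
    classify_ensemble,
    dissimilarity_matrix,
    hierarchical_cluster,
    ligand_contact_vector,
    read_structure,
    renumber,
    residue_contact_map,
    restrict_window,
    strip_hydrogens,
)
from .activity_classifier import calls_to_tsv
from .contacts import to_sparse_text
from .errors import ContactAnalysisError, EnsembleError
from .interaction_pca import ipca
from .pocket_profile import (
    POCKET_MIN_HITS,
    SCORE_MIN_TOTAL,
    agonist_score,
    contact_counts_by_class,
    mark_pocket,
)
from .conserved_contacts import CONSERVATION_THRESHOLD

log = logging.getLogger("nrcontacts")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Defaults are the standard analysis conditions: 4.5 Å heavy-atom contacts
    (4.2 Å all-atom for snapshots), neighbour exclusion |i−j| ≤ 2, common
    window 276–475, activity cutoff 60, pocket threshold 10 hits, score
    filter N_T ≥ 10, conservation threshold 0.5, average linkage.
    """

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "nrcontacts_out"
    chain: str | None = None
    numbering_offsets: dict[str, int] = field(default_factory=dict)
    crystal_cutoff: float = HEAVY_CUTOFF
    trajectory_cutoff: float = ALL_ATOM_CUTOFF
    min_seq_sep: int = MIN_SEQ_SEP
    common_window: tuple[int, int] = COMMON_WINDOW
    activity_cutoff: int = ACTIVITY_CUTOFF
    pocket_min_hits: int = POCKET_MIN_HITS
    score_min_total: int = SCORE_MIN_TOTAL
    conservation_threshold: float = CONSERVATION_THRESHOLD
    dissimilarity_metric: str = "n10"
    linkage: str = "average"
    n_modes: int = 2
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "common_window" in data:
            data["common_window"] = tuple(data["common_window"])
        return cls(**data)

    def manifest(self) -> dict:
        d = asdict(self)
        d["common_window"] = list(self.common_window)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except ContactAnalysisError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("read")
def _load_structures(cfg: RunConfig):
    structures = []
    for path in cfg.inputs:
        p = Path(path)
        s = read_structure(p.read_text(), chain=cfg.chain, structure_id=p.stem)
        offset = cfg.numbering_offsets.get(s.id, 0)
        if offset:
            s = renumber(s, offset)
        structures.append(strip_hydrogens(s))
    if not structures:
        raise EnsembleError("no input structures")
    return structures


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the crystal-ensemble analysis; returns the result bundle.

    Writes per-structure sparse contact maps, the activity TSV, the
    dissimilarity CSV and Newick dendrogram, the pocket-profile TSV, the
    interaction-PCA CSVs and a JSON manifest of every threshold used.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structures = _load_structures(cfg)

    maps = [
        residue_contact_map(s, cutoff=cfg.crystal_cutoff, min_seq_sep=cfg.min_seq_sep)
        for s in structures
    ]
    (out / "contact_maps").mkdir(exist_ok=True)
    for m in maps:
        (out / "contact_maps" / f"{m.structure_id}.txt").write_text(to_sparse_text(m))

    calls = classify_ensemble(maps, cutoff=cfg.activity_cutoff)
    (out / "activity.tsv").write_text(calls_to_tsv(calls))
    labels = {c.structure_id: c.label for c in calls}

    common = [restrict_window(m, *cfg.common_window) for m in maps]
    bundle: dict = {"structures": structures, "maps": maps, "calls": calls}
    if len(common) >= 2:
        d = dissimilarity_matrix(common, metric=cfg.dissimilarity_metric)
        tree = hierarchical_cluster(d, method=cfg.linkage)
        (out / "dissimilarity.csv").write_text(d.to_csv())
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        bundle["dissimilarity"] = d
        bundle["dendrogram"] = tree

    liganded = [s for s in structures if s.ligands]
    skipped = [s.id for s in structures if not s.ligands]
    for sid in skipped:
        log.warning("%s: no ligand entity — excluded from ligand statistics", sid)
    if liganded:
        vectors = [
            ligand_contact_vector(s, cutoff=cfg.crystal_cutoff, window=cfg.common_window)
            for s in liganded
        ]
        profile = mark_pocket(
            agonist_score(
                contact_counts_by_class(vectors, labels), min_total=cfg.score_min_total
            ),
            min_hits=cfg.pocket_min_hits,
        )
        (out / "pocket_profile.tsv").write_text(profile.to_tsv())
        bundle["profile"] = profile
        if len(vectors) >= 2:
            result = ipca(vectors, n_modes=cfg.n_modes)
            result.loadings_frame().to_csv(out / "ipca_loadings.csv", index=False)
            result.projections_frame(labels).to_csv(out / "ipca_projections.csv", index=False)
            import pandas as pd

            pd.DataFrame(
                {"mode": [f"PC{k + 1}" for k in range(len(result.eigenvalues))],
                 "eigenvalue": result.eigenvalues}
            ).to_csv(out / "ipca_eigenvalues.csv", index=False)
            bundle["ipca"] = result

    manifest = cfg.manifest()
    manifest["n_structures"] = len(structures)
    manifest["n_liganded"] = len(liganded)
    manifest["apo_skipped"] = skipped
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
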