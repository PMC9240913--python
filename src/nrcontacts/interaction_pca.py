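"""Interaction PCA of residue–ligand contact fluctuations.

Each structure α contributes a binary fingerprint L^α over residues; the
fluctuation δL_i^α = L_i^α − ⟨L_i⟩ is the deviation of residue i's ligand
contact from its ensemble mean.  The covariance

    C_ij = ⟨δL_i δL_j⟩ = (1/K) Σ_α δL_i^α δL_j^α

captures which residues gain or lose ligand contact together; its top
eigenvectors are the dominant binding patterns (e.g. canonical vs allosteric
site occupancy) and per-structure projections of δL^α onto them place each
complex on those axes.  The normalisation divides by the ensemble size K,
not K − 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import LigandContactVector
from .errors import EnsembleError
from .pocket_profile import _stack


@dataclass(frozen=True)
class IPCAResult:
    residue_indices: np.ndarray  # (n,) residues entering the decomposition
    eigenvalues: np.ndarray  # (m,) non-increasing
    eigenvectors: np.ndarray  # (n, m), orthonormal columns
    projections: np.ndarray  # (K, m)
    structure_ids: tuple[str, ...]
    mean_vector: np.ndarray  # (n,) ⟨L_i⟩
    K: int

    def loadings_frame(self):
        import pandas as pd

        cols = {f"PC{k + 1}": self.eigenvectors[:, k] for k in range(self.eigenvectors.shape[1])}
        return pd.DataFrame({"residue_index": self.residue_indices, **cols})

    def projections_frame(self, labels: dict[str, str] | None = None):
        import pandas as pd

        cols = {f"PC{k + 1}": self.projections[:, k] for k in range(self.projections.shape[1])}
        df = pd.DataFrame({"structure_id": list(self.structure_ids), **cols})
        if labels is not None:
            df["label"] = [labels.get(s, "") for s in self.structure_ids]
        return df


def contact_covariance(
    vectors: list[LigandContactVector],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance of contact fluctuations: (C, mean, residue_indices).

    C_ij = Σ_α δL_i^α δL_j^α / K with δL = L − ⟨L⟩; the diagonal is the
    Bernoulli variance p_i(1 − p_i) of each residue's contact frequency.
    """
    if len(vectors) < 2:
        raise EnsembleError("covariance requires at least two structures")
    idx, X = _stack(vectors)
    Xf = X.astype(float)
    mean = Xf.mean(axis=0)
    delta = Xf - mean
    C = delta.T @ delta / len(vectors)
    return C, mean, idx


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude component is positive (ties: first)."""
    k = int(np.argmax(np.abs(v)))
    return -v if v[k] < 0 else v


def ipca(
    vectors: list[LigandContactVector],
    n_modes: int = 2,
    orient_positive: list[str] | None = None,
) -> IPCAResult:
    """Eigendecomposition of the contact-fluctuation covariance.

    Residues never contacted in the ensemble carry no variance and are
    reported with zero loadings.  Modes are sorted by eigenvalue
    (descending; exact ties broken by lexicographic loading order) and each
    eigenvector is oriented so its largest-magnitude loading is positive.
    ``orient_positive`` optionally lists structure ids whose mean PC1
    projection should come out positive (e.g. a known allosteric-binder
    subset), flipping mode 1 when needed.
    """
    idx_all, X = _stack(vectors)
    informative = X.sum(axis=0) >= 1
    C, mean, _ = contact_covariance(vectors)
    Ci = C[np.ix_(informative, informative)]

    evals, evecs = np.linalg.eigh(Ci)
    order = np.argsort(evals)[::-1]
    # deterministic ordering among exactly degenerate eigenvalues
    order = sorted(
        order, key=lambda k: (-evals[k], tuple(np.round(-np.abs(evecs[:, k]), 12)))
    )
    evals = evals[order][:n_modes]
    modes = np.zeros((len(idx_all), len(evals)))
    for m, k in enumerate(order[: len(evals)]):
        modes[informative, m] = _canonical_sign(evecs[:, k])

    delta = X.astype(float) - mean
    proj = delta @ modes

    ids = tuple(v.structure_id for v in vectors)
    if orient_positive:
        members = [k for k, s in enumerate(ids) if s in orient_positive]
        if members and proj[members, 0].mean() < 0:
            modes[:, 0] *= -1
            proj[:, 0] *= -1
    return IPCAResult(
        residue_indices=idx_all,
        eigenvalues=evals,
        eigenvectors=modes,
        projections=proj,
        structure_ids=ids,
        mean_vector=mean,
        K=len(vectors),
    )
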