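"""Geometry utilities: Kabsch RMSD, conformer pre-filtering, hierarchical
clustering and dihedral diagnostics.

Atom order is assumed consistent across conformers of the same molecule
(true for conformational-search output); no symmetry-equivalent-atom
renumbering is attempted. RMSD defaults to heavy atoms only, since
hydrogen positions add noise without changing backbone classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .records import ConformerRecord, ValidationError


def _selected_coords(rec: ConformerRecord, selection) -> np.ndarray:
    if selection is None:
        idx = rec.heavy_atom_indices()
    elif selection == "all":
        idx = np.arange(rec.n_atoms)
    else:
        idx = np.asarray(selection, dtype=int) - 1  # user-facing indices are 1-based
        if idx.min(initial=0) < 0 or idx.max(initial=-1) >= rec.n_atoms:
            raise ValidationError(f"selection out of range for conformer {rec.id!r}")
    return rec.coords[idx], idx


def kabsch_rmsd(
    a: ConformerRecord, b: ConformerRecord, selection: Sequence[int] | str | None = None
) -> float:
    """RMSD (angstrom) after optimal rigid superposition.

    Centroids are superposed and the least-squares proper rotation is
    applied (Kabsch). ``selection`` is ``None`` for heavy atoms (the
    default), ``"all"``, or an explicit list of 1-based atom indices
    referring to the same atoms in both structures.
    """
    pa, ia = _selected_coords(a, selection)
    pb, ib = _selected_coords(b, selection)
    if pa.shape != pb.shape:
        raise ValidationError(
            f"selection sizes differ: {pa.shape[0]} vs {pb.shape[0]} atoms"
        )
    if pa.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    ea = [a.elements[i] for i in ia]
    eb = [b.elements[i] for i in ib]
    if ea != eb:
        warnings.warn(
            f"element mismatch between paired atoms of {a.id!r} and {b.id!r}",
            stacklevel=2,
        )
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem with a proper
    # rotation; the residual is recomputed explicitly because the reported
    # rssd loses precision near zero
    rot, _ = Rotation.align_vectors(pa, pb)
    resid = rot.apply(pb) - pa
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def pairwise_rmsd_matrix(
    ensemble: Sequence[ConformerRecord], selection=None
) -> np.ndarray:
    n = len(ensemble)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(ensemble[i], ensemble[j], selection)
    return m


def prefilter_conformers(
    ensemble: Sequence[ConformerRecord],
    energy_window: float = 12.0,
    rmsd_cutoff: float = 1.0,
    selection=None,
) -> list[ConformerRecord]:
    """Collate a conformational-search ensemble before expensive work.

    Conformers more than ``energy_window`` kJ/mol above the minimum are
    dropped; the survivors are scanned in ascending energy and any
    conformer within ``rmsd_cutoff`` angstrom (heavy-atom Kabsch RMSD) of
    an already-kept one is discarded as a duplicate. The ascending-energy
    scan makes the result independent of input order.
    """
    if any(r.energy is None for r in ensemble):
        raise ValidationError("prefilter requires energies on every conformer")
    if not ensemble:
        return []
    e = np.array([r.energy for r in ensemble], dtype=float)
    window = [r for r, ei in zip(ensemble, e) if ei <= e.min() + energy_window]
    window.sort(key=lambda r: (r.energy, r.id))
    kept: list[ConformerRecord] = []
    for rec in window:
        if all(kabsch_rmsd(rec, other, selection) >= rmsd_cutoff for other in kept):
            kept.append(rec)
    return kept


@dataclass
class ClusterResult:
    """Hierarchical clustering of an ensemble on pairwise Kabsch RMSD."""

    ids: tuple[str, ...]
    labels: np.ndarray          # cluster id (1-based) per conformer
    rmsd_matrix: np.ndarray     # angstrom, symmetric, zero diagonal
    merge_distance: float
    representatives: dict[int, str]  # cluster id -> conformer id

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, lab in zip(self.ids, self.labels) if lab == cluster]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conformer": self.ids,
                "cluster": self.labels,
                "representative": [
                    self.representatives[int(lab)] == cid
                    for cid, lab in zip(self.ids, self.labels)
                ],
            }
        )


def cluster_conformers(
    ensemble: Sequence[ConformerRecord],
    merge_distance: float = 0.25,
    selection=None,
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of conformers, tree cut at ``merge_distance``.

    Complete linkage by default, which yields compact ("homogeneous")
    clusters whose internal RMSD never exceeds the merge distance;
    ``single`` and ``average`` are also accepted. The representative of
    each cluster is its lowest-energy member (first by id when energies
    are absent).
    """
    if not ensemble:
        raise ValidationError("empty ensemble")
    ids = tuple(r.id for r in ensemble)
    m = pairwise_rmsd_matrix(ensemble, selection)
    if len(ensemble) == 1:
        labels = np.array([1])
    else:
        z = hierarchy.linkage(squareform(m, checks=False), method=linkage)
        labels = hierarchy.fcluster(z, t=merge_distance, criterion="distance")
    reps: dict[int, str] = {}
    for lab in np.unique(labels):
        members = [r for r, l in zip(ensemble, labels) if l == lab]
        if all(r.energy is not None for r in members):
            rep = min(members, key=lambda r: (r.energy, r.id))
        else:
            rep = min(members, key=lambda r: r.id)
        reps[int(lab)] = rep.id
    return ClusterResult(
        ids=ids,
        labels=labels,
        rmsd_matrix=m,
        merge_distance=merge_distance,
        representatives=reps,
    )


def dihedral(conformer: ConformerRecord, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion angle i-j-k-l in degrees, IUPAC convention
    (cis = 0, range (-180, 180]); atom indices are 1-based."""
    if len({i, j, k, l}) != 4:
        raise ValidationError("dihedral needs four distinct atoms")
    p = conformer.coords[np.array([i, j, k, l]) - 1]
    b0, b1, b2 = p[0] - p[1], p[2] - p[1], p[3] - p[2]
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1  # components perpendicular to the j-k axis
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValidationError("collinear atoms: dihedral undefined")
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    return float(180.0 if np.isclose(ang, -180.0) else ang)
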