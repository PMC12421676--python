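"""Bilayer-aware clustering of peptide poses.

Structures are superposed with a two-dimensional Kabsch alignment: the
optimal in-plane (x, y) rotation and translation is applied while z
coordinates are never translated or rotated, so differences in insertion
depth contribute fully to the subsequent three-dimensional RMSD.  Pairwise
RMSDs over strided structures from all trajectories and both peptide copies
(pooled in the upper-leaflet convention) feed the greedy neighbor-count
clustering of Daura et al., and populated clusters (probability of
occurrence > 1%) are summarized with cluster-conditioned structural
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TrajectorySet, iter_peptide_views, peptide_views
from .peptide import (contact_matrix_frames, radius_of_gyration, end_to_end)


# ---------------------------------------------------------------------------
# 2D Kabsch
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 2x2, proper (det = +1)
    translation: np.ndarray       # in-plane translation applied to Y
    rmsd: np.ndarray | float      # over x, y, z after in-plane alignment


def _kabsch2d_rotations(X, Y):
    """Batch optimal in-plane rotations (2x2 SVD with reflection guard).

    X, Y: (..., n_atoms, 2) centered coordinate sets; returns (..., 2, 2)
    proper rotations maximizing overlap of Y onto X.
    """
    C = np.einsum("...ai,...aj->...ij", Y, X)   # cross-covariance
    U, _, Vt = np.linalg.svd(C)
    det = np.linalg.det(U @ Vt)
    D = np.zeros_like(C)
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = np.sign(det) + (det == 0)
    return np.swapaxes(U @ D @ Vt, -1, -2)


def kabsch2d_align(X: np.ndarray, Y: np.ndarray) -> AlignmentResult:
    """Align Y onto X with the in-plane-only Kabsch superposition.

    X, Y: (n_atoms, 3) with matching atom order.  The optimal 2D rotation +
    translation minimizes the xy-RMSD; z is untouched (bit-identical), and
    the reported RMSD runs over all three coordinates.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.shape[0] < 2:
        raise ValueError("need >= 2 atoms with matching shapes")
    cx = X[:, :2].mean(axis=0)
    cy = Y[:, :2].mean(axis=0)
    R = _kabsch2d_rotations(X[:, :2] - cx, Y[:, :2] - cy)
    xy = (Y[:, :2] - cy) @ R.T + cx
    aligned = np.concatenate([xy, Y[:, 2:3]], axis=1)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - X) ** 2, axis=1))))
    return AlignmentResult(rotation=R, translation=cx - cy @ R.T, rmsd=rmsd)


# ---------------------------------------------------------------------------
# pairwise RMSD over sampled structures
# ---------------------------------------------------------------------------

@dataclass
class StructureSample:
    """Strided peptide structures pooled over trajectories and copies."""

    coords: np.ndarray            # (n_structures, n_atoms, 3)
    trajectory_id: np.ndarray
    copy: np.ndarray
    frame: np.ndarray             # source frame index within the trajectory
    stride: int


def sample_structures(trajset: TrajectorySet, frame_stride: int = 10,
                      atoms: str = "heavy") -> StructureSample:
    """Every ``frame_stride``-th canonicalized peptide structure.

    ``atoms``: "heavy" (default) or "ca"."""
    coords, tids, copies, frames = [], [], [], []
    for v in iter_peptide_views(trajset):
        topo = v.topology
        if atoms == "ca":
            sel = np.flatnonzero(topo.peptide_mask(v.copy)
                                 & (topo.atom_names == "CA"))
        else:
            sel = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        idx = np.arange(0, v.n_frames, frame_stride)
        coords.append(v.coords[idx][:, sel])
        tids.append(np.full(len(idx), v.trajectory_id))
        copies.append(np.full(len(idx), v.copy))
        frames.append(idx)
    return StructureSample(coords=np.concatenate(coords),
                           trajectory_id=np.concatenate(tids),
                           copy=np.concatenate(copies),
                           frame=np.concatenate(frames), stride=frame_stride)


def pairwise_rmsd(sample_or_trajset, frame_stride: int = 10) -> np.ndarray:
    """Symmetric matrix of 2D-Kabsch-aligned 3D RMSDs.

    Accepts a :class:`StructureSample` or a TrajectorySet (strided first).
    """
    if isinstance(sample_or_trajset, TrajectorySet):
        sample = sample_structures(sample_or_trajset, frame_stride)
    else:
        sample = sample_or_trajset
    S = np.asarray(sample.coords, float)
    n, n_at, _ = S.shape
    xy = S[:, :, :2] - S[:, :, :2].mean(axis=1, keepdims=True)
    z = S[:, :, 2]
    out = np.zeros((n, n))
    # batch over reference structures
    for i in range(n - 1):
        Yc = xy[i + 1:]
        R = _kabsch2d_rotations(np.broadcast_to(xy[i], Yc.shape), Yc)
        rot = np.einsum("bij,baj->bai", R, Yc)
        dxy = rot - xy[i][None]
        dz = z[i + 1:] - z[i][None]
        msd = (np.sum(dxy ** 2, axis=(1, 2))
               + np.sum(dz ** 2, axis=1)) / n_at
        out[i, i + 1:] = np.sqrt(msd)
    out += out.T
    return out


# ---------------------------------------------------------------------------
# Daura clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    centroid: int
    members: np.ndarray
    probability: float
    populated: bool


@dataclass
class ClusterResult:
    clusters: list
    membership: np.ndarray        # cluster index per structure
    cutoff: float
    sample: StructureSample | None = None
    profiles: list = field(default_factory=list)

    @property
    def n_populated(self):
        return sum(c.populated for c in self.clusters)

    def capture_fraction(self, top_k=None):
        ps = [c.probability for c in self.clusters
              if c.populated][:top_k]
        return float(np.sum(ps))


def daura_cluster(rmsd_matrix: np.ndarray, cutoff: float = 5.4,
                  populated_threshold: float = 0.01,
                  sample: StructureSample | None = None) -> ClusterResult:
    """Greedy neighbor-count clustering (Daura et al.).

    Repeatedly take the structure with the most remaining neighbors within
    ``cutoff`` as a centroid, remove it and its neighbors as one cluster;
    ties in neighbor count break toward the lower structure index so the
    result is deterministic.
    """
    M = np.asarray(rmsd_matrix)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    n = M.shape[0]
    neigh = (M < cutoff)
    np.fill_diagonal(neigh, True)
    alive = np.ones(n, bool)
    membership = np.full(n, -1)
    clusters = []
    while alive.any():
        counts = (neigh & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest tied index
        members = np.flatnonzero(neigh[center] & alive)
        membership[members] = len(clusters)
        prob = len(members) / n
        clusters.append(Cluster(centroid=center, members=members,
                                probability=prob,
                                populated=prob > populated_threshold))
        alive[members] = False
    return ClusterResult(clusters=clusters, membership=membership,
                         cutoff=cutoff, sample=sample)


def cutoff_sweep(rmsd_matrix, cutoffs, populated_threshold=0.01):
    """Capture fraction of populated clusters across candidate cutoffs."""
    out = []
    for c in cutoffs:
        res = daura_cluster(rmsd_matrix, c, populated_threshold)
        out.append((float(c), res.n_populated, res.capture_fraction()))
    return out


# ---------------------------------------------------------------------------
# cluster-conditioned profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfile:
    cluster: int
    probability: float
    centroid: int
    n_members: int
    mean_z: np.ndarray | None = None          # <z(i; c)>
    mean_contacts: float | None = None        # <C(c)>
    mean_rg: float | None = None
    mean_ree: float | None = None
    mean_turn: float | None = None
    delta_D: float | None = None
    scd_contrast: float | None = None
    low_n: bool = False


def cluster_profiles(result: ClusterResult, trajset: TrajectorySet,
                     analyses=("depth", "contacts", "rg", "ree"),
                     ss_assignments=None, bilayer_analyses=False,
                     r_c: float = 13.0) -> list[ClusterProfile]:
    """Structural summaries per populated cluster.

    ``ss_assignments``: optional dict trajectory_id -> SSAssignment (frame
    order matching the trajectory) for turn content.  With
    ``bilayer_analyses`` the cluster-conditioned thickness indentation and
    contact-split S_CD contrast are recomputed on each cluster's frames.
    """
    from . import bilayer as _bl

    sample = result.sample
    if sample is None:
        raise ValueError("cluster result has no structure sample attached")
    views = {(v.trajectory_id, v.copy): v for v in peptide_views(trajset)}
    topo = trajset.topology
    profiles = []
    for c_idx, cl in enumerate(result.clusters):
        if not cl.populated:
            continue
        mem = cl.members
        prof = ClusterProfile(cluster=c_idx, probability=cl.probability,
                              centroid=int(cl.centroid),
                              n_members=len(mem), low_n=len(mem) < 2)
        coords = sample.coords[mem]
        if "depth" in analyses:
            # side-chain atoms within the sampled (heavy) atom set
            v0 = next(iter(views.values()))
            sel = np.flatnonzero(topo.peptide_heavy_mask(v0.copy))
            sc_global = topo.sidechain_indices(v0.copy)
            sc_local = np.searchsorted(sel, sc_global)
            prof.mean_z = coords[:, sc_local, 2].mean(axis=0)
        if "contacts" in analyses:
            v0 = next(iter(views.values()))
            groups_g = topo.residue_atoms(v0.copy)
            sel = np.flatnonzero(topo.peptide_heavy_mask(v0.copy))
            heavy_local = [np.searchsorted(sel, g[topo.heavy[g]])
                           for g in groups_g]
            mats = contact_matrix_frames(coords, heavy_local)
            iu = np.triu_indices(len(heavy_local), k=2)
            prof.mean_contacts = float(mats[:, iu[0], iu[1]].sum(axis=1)
                                       .mean())
        if "rg" in analyses:
            prof.mean_rg = float(np.mean(radius_of_gyration(coords)))
        if "ree" in analyses:
            # first/last residue CA within the heavy-atom selection
            v0 = next(iter(views.values()))
            sel = np.flatnonzero(topo.peptide_heavy_mask(v0.copy))
            names = topo.atom_names[sel]
            resl = topo.resid_local[sel]
            ca = np.flatnonzero(names == "CA")
            first = ca[np.argmin(resl[ca])]
            last = ca[np.argmax(resl[ca])]
            prof.mean_ree = float(np.mean(np.linalg.norm(
                coords[:, first] - coords[:, last], axis=1)))
        if ss_assignments is not None:
            turns = []
            for m in mem:
                tid = int(sample.trajectory_id[m])
                fr = int(sample.frame[m])
                a = ss_assignments.get(tid)
                if a is not None and fr < a.n_frames:
                    turns.append((a.labels[fr] == "T").mean())
            prof.mean_turn = float(np.mean(turns)) if turns else None
        if bilayer_analyses:
            member_frames = {}
            for m in mem:
                member_frames.setdefault(
                    (int(sample.trajectory_id[m]), int(sample.copy[m])),
                    set()).add(int(sample.frame[m]))

            def _filter(v):
                ok = np.zeros(v.n_frames, bool)
                for f in member_frames.get((v.trajectory_id, v.copy), ()):
                    ok[f] = True
                return ok

            fld = _bl.density_field(trajset, frame_filter=_filter)
            th = _bl.thickness_profile(fld, r_c=r_c)
            prof.delta_D = th.delta_D_center
            # contact-split S_CD contrast on member frames
            sub_views = []
            for v in peptide_views(trajset):
                ok = _filter(v)
                if ok.any():
                    import copy as _copy
                    vv = _copy.copy(v)
                    vv.coords = v.coords[ok]
                    vv.box = v.box[ok]
                    vv.z_P = v.z_P[ok]
                    sub_views.append(vv)
            op = _bl.s_cd(sub_views, contact_split=True)
            if op.minus_scd_contact is not None:
                a = np.nanmean(op.minus_scd)
                b = np.nanmean(op.minus_scd_contact)
                prof.scd_contrast = float((a - b) / a) if a else None
        profiles.append(prof)
    result.profiles = profiles
    return profiles
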