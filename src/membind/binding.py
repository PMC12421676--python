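"""Residue-level binding characterization.

Insertion-depth series from side-chain centers of mass (after leaflet
canonicalization), depth histograms, the inserted / surface-bound / unbound
classification against the leaflet phosphorus plane with a 6.5 A interfacial
margin, lipid and water coordination counts, hydrogen-bonded contact
fractions, and tandem lipid coordination between residue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (ROLE_LIPID, ROLE_WATER, PeptideView, TrajectorySet,
                   iter_peptide_views)
from .peptide import (CONTACT_CUTOFF, HBOND_ANGLE, HBOND_DISTANCE,
                      hydrogen_bonds)

SURFACE_MARGIN = 6.5

try:
    from MDAnalysis.lib.distances import capped_distance
except Exception:  # pragma: no cover - MDAnalysis is a hard dependency
    capped_distance = None


def _pairs_within(ref, other, cutoff, box_xy=None):
    """Index pairs (i, j) with |ref_i - other_j| < cutoff.

    Uses MDAnalysis' grid search with an orthorhombic box applying the
    lateral minimum-image convention only (huge z extent).
    """
    box = None
    if box_xy is not None:
        box = np.array([box_xy[0], box_xy[1], 1e6, 90.0, 90.0, 90.0],
                       np.float32)
    pairs = capped_distance(ref.astype(np.float32),
                            other.astype(np.float32),
                            max_cutoff=cutoff, box=box,
                            return_distances=False)
    return pairs


# ---------------------------------------------------------------------------
# depths and state classification
# ---------------------------------------------------------------------------

@dataclass
class DepthSeries:
    """Side-chain center-of-mass distance from the bilayer midplane.

    ``z`` is (n_frames, n_res) for one canonical peptide view; ``z_P`` the
    per-frame phosphorus-plane height of the analyzed leaflet.
    """

    z: np.ndarray
    z_P: np.ndarray
    trajectory_id: int
    copy: int


@dataclass
class StateProbabilities:
    P_inserted: np.ndarray
    P_surface: np.ndarray
    P_unbound: np.ndarray
    se: np.ndarray                    # (3, n_res) SE across trajectories
    binding_probability: float
    binding_se: float | None
    n_trajectories: int

    def as_matrix(self):
        return np.stack([self.P_inserted, self.P_surface, self.P_unbound])


def residue_depths(trajset_or_views, whole_residue: bool = False):
    """Per-residue depth series for every canonical (trajectory, copy) view.

    ``z(i)`` is the side-chain center of mass (the side-chain centroid
    pseudo-atom in the reduced model; CA fallback when a residue has no side
    chain).  With ``whole_residue`` the mass-weighted center of all residue
    atoms is used instead.
    """
    views = _as_views(trajset_or_views)
    out = []
    for v in views:
        topo = v.topology
        if whole_residue:
            z = np.empty((v.n_frames, len(v.residue_atoms())))
            for i, atoms in enumerate(v.residue_atoms()):
                w = topo.masses[atoms] / topo.masses[atoms].sum()
                z[:, i] = v.coords[:, atoms, 2] @ w
        else:
            sc = v.sidechain_indices()
            z = v.coords[:, sc, 2]
        out.append(DepthSeries(z=z, z_P=v.z_P, trajectory_id=v.trajectory_id,
                               copy=v.copy))
    return out


def depth_histogram(depths, bin_width: float = 0.5, z_range=(-5.0, 40.0)):
    """Normalized P(z; i) grid: sum_z P(z; i) * dz = 1 for every residue."""
    if isinstance(depths, DepthSeries):
        depths = [depths]
    edges = np.arange(z_range[0], z_range[1] + bin_width, bin_width)
    z_all = np.concatenate([d.z for d in depths], axis=0)
    n_res = z_all.shape[1]
    grid = np.empty((len(edges) - 1, n_res))
    for i in range(n_res):
        counts, _ = np.histogram(z_all[:, i], bins=edges)
        total = counts.sum()
        grid[:, i] = counts / (max(total, 1) * bin_width)
    return grid, edges


def classify_states(depths, margin: float = SURFACE_MARGIN,
                    binding_mode: str = "depth") -> StateProbabilities:
    """Inserted / surface-bound / unbound probabilities per residue.

    Per frame: inserted if z(i) < z_P, surface-bound if z_P <= z(i) <
    z_P + margin, unbound otherwise.  The peptide counts as bound in a frame
    iff at least one residue is inserted or surface-bound
    (``binding_mode='depth'``).  SEs treat each trajectory as one sample.
    """
    if isinstance(depths, DepthSeries):
        depths = [depths]
    per_traj = {}
    per_traj_bound = {}
    for d in depths:
        rel = d.z - d.z_P[:, None]
        state = np.where(rel < 0, 0, np.where(rel < margin, 1, 2))
        probs = np.stack([(state == s).mean(axis=0) for s in range(3)])
        per_traj.setdefault(d.trajectory_id, []).append(probs)
        bound = (state <= 1).any(axis=1).mean()
        per_traj_bound.setdefault(d.trajectory_id, []).append(bound)
    traj_means = np.array([np.mean(v, axis=0) for v in per_traj.values()])
    mean = traj_means.mean(axis=0)
    n = len(traj_means)
    se = (traj_means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.full_like(mean, np.nan))
    bmeans = np.array([np.mean(v) for v in per_traj_bound.values()])
    b_se = float(bmeans.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return StateProbabilities(
        P_inserted=mean[0], P_surface=mean[1], P_unbound=mean[2], se=se,
        binding_probability=float(bmeans.mean()), binding_se=b_se,
        n_trajectories=n)


# ---------------------------------------------------------------------------
# lipid coordination
# ---------------------------------------------------------------------------

@dataclass
class LipidContactProfile:
    """Average lipid coordination numbers per residue.

    ``per_residue`` = <C_l(i)>: lipids with any heavy atom within the cutoff
    of residue i, counted once per lipid per frame.  ``per_group`` (5, n_res)
    resolves the counts by structural group G1..G5; a group contact is
    "stable" if <C_l(i,k)> >= 1.  ``hbonded`` = <C_l,hb(i)>: contacts that
    include at least one residue-lipid hydrogen bond.
    """

    per_residue: np.ndarray
    per_group: np.ndarray
    hbonded: np.ndarray
    se_per_residue: np.ndarray
    se_per_group: np.ndarray
    n_trajectories: int

    @property
    def stable(self):
        return self.per_group >= 1.0

    def hbond_fraction(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.per_residue > 0,
                            self.hbonded / self.per_residue, 0.0)

    def to_csv(self, path):
        import pandas as pd
        n = len(self.per_residue)
        df = pd.DataFrame({"residue": np.arange(1, n + 1),
                           "C_l": self.per_residue,
                           "C_l_se": self.se_per_residue,
                           "C_l_hb": self.hbonded})
        for k in range(5):
            df[f"G{k + 1}"] = self.per_group[k]
        df.to_csv(path, index=False)


def _contact_lipids_frame(coords, pep_heavy, pep_res, lip_heavy, lip_mol,
                          lip_group, cutoff, box_xy):
    """(residue, lipid) and (residue, lipid, group) contact sets, one frame."""
    pairs = _pairs_within(coords[pep_heavy], coords[lip_heavy], cutoff,
                          box_xy)
    if len(pairs) == 0:
        return set(), set()
    ri = pep_res[pairs[:, 0]]
    mol = lip_mol[pairs[:, 1]]
    grp = lip_group[pairs[:, 1]]
    rl = set(zip(ri.tolist(), mol.tolist()))
    rlg = set(zip(ri.tolist(), mol.tolist(), grp.tolist()))
    return rl, rlg


def lipid_contacts(trajset_or_views, cutoff: float = CONTACT_CUTOFF,
                   with_hbonds: bool = True,
                   hbond_distance: float = HBOND_DISTANCE,
                   hbond_angle: float = HBOND_ANGLE) -> LipidContactProfile:
    """Lipid coordination profile <C_l(i)>, <C_l(i,k)> and <C_l,hb(i)>."""
    import itertools
    views = iter(_as_views(trajset_or_views))
    first = next(views)
    n_res = len(first.residue_atoms())
    per_traj = {}
    for v in itertools.chain([first], views):
        topo = v.topology
        pep_heavy = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        res_of = topo.resid_local[pep_heavy] - 1
        lip_heavy = np.flatnonzero(topo.lipid_heavy_mask)
        lip_mol = topo.molecule_id[lip_heavy]
        lip_grp = topo.lipid_group[lip_heavy]
        # donors/acceptors for the H-bond refinement
        pep_all = np.flatnonzero(topo.peptide_mask(v.copy))
        pd_mask = topo.is_donor[pep_all]
        pa_mask = topo.is_acceptor[pep_all]
        lip_all = np.flatnonzero(topo.role == ROLE_LIPID)
        la_mask = topo.is_acceptor[lip_all]
        ld_mask = topo.is_donor[lip_all]
        cl = np.zeros(n_res)
        clk = np.zeros((5, n_res))
        clhb = np.zeros(n_res)
        F = v.n_frames
        for f in range(F):
            c = v.coords[f]
            rl, rlg = _contact_lipids_frame(
                c, pep_heavy, res_of, lip_heavy, lip_mol, lip_grp, cutoff,
                v.box[f][:2])
            for r, _ in rl:
                cl[r] += 1
            for r, _, g in rlg:
                if g >= 1:
                    clk[g - 1, r] += 1
            if with_hbonds and rl:
                hb_pairs = _residue_lipid_hbonds(
                    c, topo, pep_all, pd_mask, pa_mask, lip_all, la_mask,
                    ld_mask, hbond_distance, hbond_angle)
                for r, mol in rl:
                    if (r, mol) in hb_pairs:
                        clhb[r] += 1
        arr = np.concatenate([cl[None] / F, clk / F, clhb[None] / F])
        per_traj.setdefault(v.trajectory_id, []).append(arr)
    traj_means = np.array([np.mean(m, axis=0) for m in per_traj.values()])
    mean = traj_means.mean(axis=0)
    n = len(traj_means)
    se = (traj_means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.full_like(mean, np.nan))
    return LipidContactProfile(
        per_residue=mean[0], per_group=mean[1:6], hbonded=mean[6],
        se_per_residue=se[0], se_per_group=se[1:6], n_trajectories=n)


def _residue_lipid_hbonds(c, topo, pep_all, pd_mask, pa_mask, lip_all,
                          la_mask, ld_mask, distance, angle):
    """Set of (residue_index0, lipid_molecule_id) joined by >= 1 H-bond."""
    out = set()
    # peptide donor -> lipid acceptor
    don = pep_all[pd_mask]
    acc = lip_all[la_mask]
    for d, _, a in hydrogen_bonds(c, don, topo.donor_h[don], acc,
                                  distance, angle):
        out.add((int(topo.resid_local[d] - 1), int(topo.molecule_id[a])))
    # lipid donor -> peptide acceptor (none for phosphatidylcholine, but
    # supported for completeness)
    don = lip_all[ld_mask]
    if len(don):
        acc = pep_all[pa_mask]
        for d, _, a in hydrogen_bonds(c, don, topo.donor_h[don], acc,
                                      distance, angle):
            out.add((int(topo.resid_local[a] - 1), int(topo.molecule_id[d])))
    return out


def hbond_contact_fraction(trajset_or_views, **kwargs):
    """<C_l,hb(i)> and the hydrogen-bonded fraction of lipid contacts."""
    prof = lipid_contacts(trajset_or_views, with_hbonds=True, **kwargs)
    return prof.hbonded, prof.hbond_fraction()


def tandem_coordination(trajset_or_views, resA: int, resB: int,
                        cutoff: float = CONTACT_CUTOFF):
    """Mean number of lipids simultaneously contacting residues A and B.

    Returns ``(mean_shared, shared_fraction_A, shared_fraction_B)`` where the
    fractions are shared lipids over each residue's own contact count.
    """
    views = _as_views(trajset_or_views)
    shared_counts, a_counts, b_counts, total = 0.0, 0.0, 0.0, 0
    for v in views:
        topo = v.topology
        pep_heavy = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        res_of = topo.resid_local[pep_heavy] - 1
        lip_heavy = np.flatnonzero(topo.lipid_heavy_mask)
        lip_mol = topo.molecule_id[lip_heavy]
        grp = topo.lipid_group[lip_heavy]
        for f in range(v.n_frames):
            rl, _ = _contact_lipids_frame(
                v.coords[f], pep_heavy, res_of, lip_heavy, lip_mol, grp,
                cutoff, v.box[f][:2])
            sa = {m for r, m in rl if r == resA - 1}
            sb = {m for r, m in rl if r == resB - 1}
            shared_counts += len(sa & sb)
            a_counts += len(sa)
            b_counts += len(sb)
            total += 1
    mean_shared = shared_counts / max(total, 1)
    fa = shared_counts / a_counts if a_counts else 0.0
    fb = shared_counts / b_counts if b_counts else 0.0
    return mean_shared, fa, fb


# ---------------------------------------------------------------------------
# water coordination
# ---------------------------------------------------------------------------

def water_contacts(trajset_or_views, cutoff: float = CONTACT_CUTOFF,
                   reference: float | None = None):
    """Mean number of water molecules in contact with the peptide.

    A water counts once per frame if any of its atoms is within ``cutoff``
    of any peptide heavy atom.  With ``reference`` (e.g. the count for the
    peptide free in water) the relative change 1 - bound/reference is also
    returned.
    """
    views = _as_views(trajset_or_views)
    per_traj = {}
    for v in views:
        topo = v.topology
        pep_heavy = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        wat = np.flatnonzero(topo.role == ROLE_WATER)
        wat_mol = topo.molecule_id[wat]
        counts = np.empty(v.n_frames)
        for f in range(v.n_frames):
            pairs = _pairs_within(v.coords[f][pep_heavy],
                                  v.coords[f][wat], cutoff, v.box[f][:2])
            counts[f] = (len(np.unique(wat_mol[pairs[:, 1]]))
                         if len(pairs) else 0)
        per_traj.setdefault(v.trajectory_id, []).append(counts.mean())
    means = np.array([np.mean(v) for v in per_traj.values()])
    mean = float(means.mean())
    n = len(means)
    se = float(means.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    if reference is None:
        return mean, se, None
    return mean, se, 1.0 - mean / reference


def _as_views(x):
    if isinstance(x, TrajectorySet):
        return iter_peptide_views(x)
    if isinstance(x, PeptideView):
        return [x]
    return x
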