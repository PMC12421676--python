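"""Bilayer response to the bound peptide.

Cylindrical lipid/water number-density fields n(r, z) around the peptide
lateral center, equal-density bilayer thickness tracing D(r) and the
indentation measures delta-D, region-averaged densities inside/outside the
binding footprint r_c, and carbon-deuterium order parameters S_CD for the
sn-2 chains with an optional split by peptide contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (ROLE_LIPID, ROLE_WATER, TrajectorySet,
                   iter_peptide_views)
from .peptide import CONTACT_CUTOFF
from .binding import _pairs_within, _as_views

R_C_DEFAULT = 13.0


# ---------------------------------------------------------------------------
# density fields
# ---------------------------------------------------------------------------

@dataclass
class DensityField:
    """Binned number densities on an (r, z) grid (A^-3).

    ``lipid``/``water`` have shape (n_r, n_z); bin volumes are the exact
    annulus volumes pi (r2^2 - r1^2) dz.  The field is accumulated per
    canonical peptide view (peptide kept in the upper leaflet, field
    re-centered on the peptide's lateral center every frame) and averaged.
    """

    lipid: np.ndarray
    water: np.ndarray
    r_edges: np.ndarray
    z_edges: np.ndarray
    n_frames: int

    @property
    def r_centers(self):
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self):
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def bin_volumes(self):
        dv_r = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        dz = np.diff(self.z_edges)
        return dv_r[:, None] * dz[None, :]

    def to_csv(self, path, which="lipid"):
        import pandas as pd
        arr = getattr(self, which)
        df = pd.DataFrame(arr, index=self.r_centers, columns=self.z_centers)
        df.index.name = "r"
        df.to_csv(path)


def density_field(trajset_or_views, r_max: float | None = None,
                  dr: float = 1.0, dz: float = 1.0,
                  z_max: float = 30.0,
                  frame_filter=None) -> DensityField:
    """Lipid heavy-atom and water number densities around the peptide.

    ``frame_filter(view) -> bool array over frames`` restricts the
    accumulation (used for cluster-conditioned fields).  ``r_max`` beyond
    half the smaller lateral box length is truncated with a warning.
    """
    import itertools
    views = iter(_as_views(trajset_or_views))
    first = next(views)
    views = itertools.chain([first], views)
    box_half = float(first.box[:, :2].min()) / 2.0
    if r_max is None:
        r_max = box_half
    elif r_max > box_half:
        warnings.warn(f"r_max {r_max} exceeds half box ({box_half:.1f} A); "
                      "truncated", stacklevel=2)
        r_max = box_half
    r_edges = np.arange(0.0, r_max + dr, dr)
    z_edges = np.arange(-z_max, z_max + dz, dz)
    lip_counts = np.zeros((len(r_edges) - 1, len(z_edges) - 1))
    wat_counts = np.zeros_like(lip_counts)
    n_frames = 0
    for v in views:
        topo = v.topology
        pep_heavy = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        lip = np.flatnonzero(topo.lipid_heavy_mask)
        wat = np.flatnonzero(topo.role == ROLE_WATER)
        keep = (np.ones(v.n_frames, bool) if frame_filter is None
                else np.asarray(frame_filter(v), bool))
        lx, ly = v.box[0, 0], v.box[0, 1]
        for f in np.flatnonzero(keep):
            c = v.coords[f]
            center = c[pep_heavy, :2].mean(axis=0)
            for idx, acc in ((lip, lip_counts), (wat, wat_counts)):
                d = c[idx, :2] - center[None]
                d[:, 0] -= lx * np.round(d[:, 0] / lx)
                d[:, 1] -= ly * np.round(d[:, 1] / ly)
                r = np.hypot(d[:, 0], d[:, 1])
                h, _, _ = np.histogram2d(r, c[idx, 2],
                                         bins=(r_edges, z_edges))
                acc += h
            n_frames += 1
    field = DensityField(lipid=lip_counts, water=wat_counts,
                         r_edges=r_edges, z_edges=z_edges, n_frames=n_frames)
    vol = field.bin_volumes * max(n_frames, 1)
    field.lipid = field.lipid / vol
    field.water = field.water / vol
    return field


def region_density(field: DensityField, r_c: float = R_C_DEFAULT,
                   leaflet: str = "upper", z_slab=None):
    """Volume-weighted mean lipid density near (r < r_c) vs away (r >= r_c).

    The leaflet slab defaults to z in [0, 17.4] for the upper leaflet and
    its mirror for the lower.
    """
    if z_slab is None:
        z_slab = (0.0, 17.4) if leaflet == "upper" else (-17.4, 0.0)
    zc = field.z_centers
    zm = (zc >= z_slab[0]) & (zc < z_slab[1])
    rc = field.r_centers
    vol = field.bin_volumes
    out = []
    for rm in (rc < r_c, rc >= r_c):
        w = vol[np.ix_(rm, zm)]
        d = field.lipid[np.ix_(rm, zm)]
        out.append(float((d * w).sum() / w.sum()))
    return tuple(out)


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

@dataclass
class ThicknessProfile:
    r_centers: np.ndarray
    z_upper: np.ndarray           # z+(r), NaN where undefined
    z_lower: np.ndarray
    D: np.ndarray                 # z+ - z-
    r_c: float
    delta_D_near: float
    delta_D_center: float

    def to_csv(self, path):
        import pandas as pd
        pd.DataFrame({"r": self.r_centers, "z_plus": self.z_upper,
                      "z_minus": self.z_lower, "D": self.D}
                     ).to_csv(path, index=False)


def _crossing(zc, lip, wat, upper: bool):
    """Equal-density z by linear interpolation of (lipid - water).

    Scans outward from the bilayer center for the first strict sign change;
    the bracket is symmetric under swapping the lipid and water fields."""
    diff = lip - wat
    idx = np.arange(len(zc) - 1) if upper else np.arange(len(zc) - 1)[::-1]
    for k in idx:
        a, b = (k, k + 1) if upper else (k + 1, k)
        if upper and zc[a] < 0:
            continue
        if not upper and zc[a] > 0:
            continue
        d0, d1 = diff[a], diff[b]
        if (d0 > 0 > d1) or (d0 < 0 < d1):
            z0, z1 = zc[a], zc[b]
            return z0 + (z1 - z0) * d0 / (d0 - d1)
    return np.nan


def thickness_profile(field: DensityField, r_c: float = R_C_DEFAULT
                      ) -> ThicknessProfile:
    """Equal lipid/water-density thickness D(r) and indentation measures.

    delta_D_near = mean D(r >= r_c) - mean D(r < r_c);
    delta_D_center = mean D(r >= r_c) - D(r ~ 0).  Radii without a density
    crossing are masked with a warning.
    """
    zc = field.z_centers
    n_r = len(field.r_centers)
    z_up = np.full(n_r, np.nan)
    z_lo = np.full(n_r, np.nan)
    for i in range(n_r):
        z_up[i] = _crossing(zc, field.lipid[i], field.water[i], True)
        z_lo[i] = _crossing(zc, field.lipid[i], field.water[i], False)
    D = z_up - z_lo
    if np.isnan(D).any():
        warnings.warn(f"{int(np.isnan(D).sum())} radial bin(s) without an "
                      "equal-density crossing; masked", stacklevel=2)
    rc = field.r_centers
    near = D[(rc < r_c)]
    away = D[(rc >= r_c)]
    d_away = float(np.nanmean(away)) if len(away) else np.nan
    d_near = float(np.nanmean(near)) if len(near) else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d_center = float(np.nanmean(D[rc < 3.0]))  # innermost annuli
    return ThicknessProfile(
        r_centers=rc, z_upper=z_up, z_lower=z_lo, D=D, r_c=r_c,
        delta_D_near=d_away - d_near, delta_D_center=d_away - d_center)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterProfile:
    """-S_CD per sn-2 carbon, optionally split by peptide contact."""

    carbons: np.ndarray           # carbon positions (2..14)
    minus_scd: np.ndarray         # pooled (or not-in-contact when split)
    minus_scd_contact: np.ndarray | None
    se: np.ndarray
    se_contact: np.ndarray | None
    n_trajectories: int

    def mean_minus_scd(self, contact=False):
        arr = self.minus_scd_contact if contact else self.minus_scd
        return float(np.nanmean(arr))

    def to_csv(self, path):
        import pandas as pd
        df = pd.DataFrame({"carbon": self.carbons,
                           "minus_scd": self.minus_scd, "se": self.se})
        if self.minus_scd_contact is not None:
            df["minus_scd_contact"] = self.minus_scd_contact
            df["se_contact"] = self.se_contact
        df.to_csv(path, index=False)


def _sn2_ch_indices(topo):
    """(carbon_idx, h_idx, carbon_position) triples for all sn-2 C-H bonds."""
    lip_mols = np.unique(topo.molecule_id[topo.role == ROLE_LIPID])
    if len(lip_mols) == 0:
        raise ValueError("no lipids in topology")
    out_c, out_h, out_pos, out_mol = [], [], [], []
    for m in lip_mols:
        atoms = np.flatnonzero(topo.molecule_id == m)
        names = {topo.atom_names[a]: a for a in atoms}
        for pos in range(2, 15):
            cn = f"C2{pos}"
            if cn not in names:
                raise ValueError(f"missing sn-2 carbon {cn}")
            for hn in (f"H{pos}R", f"H{pos}S"):
                if hn not in names:
                    raise ValueError(f"missing sn-2 hydrogen {hn} "
                                     f"(carbon {cn})")
                out_c.append(names[cn])
                out_h.append(names[hn])
                out_pos.append(pos)
                out_mol.append(m)
    return (np.array(out_c), np.array(out_h), np.array(out_pos),
            np.array(out_mol))


def s_cd(trajset_or_views, contact_split: bool = False,
         cutoff: float = CONTACT_CUTOFF) -> OrderParameterProfile:
    """Carbon-deuterium order parameter for the sn-2 chains.

    S_CD(i) = <(3 cos^2 theta - 1)/2> over both hydrogens, frames and
    lipids, with theta the C-H angle to the bilayer normal; reported as
    -S_CD by convention.  With ``contact_split`` lipids are partitioned per
    frame by any-heavy-atom contact with the peptide (< cutoff).
    """
    views = list(_as_views(trajset_or_views)) if not isinstance(
        trajset_or_views, TrajectorySet) else None
    if views is None:
        views = iter_peptide_views(trajset_or_views)
        topo = trajset_or_views.topology
    else:
        topo = views[0].topology
    ci, hi, pos, mol = _sn2_ch_indices(topo)
    carbons = np.arange(2, 15)
    per_traj = {}
    for v in views:
        pep_heavy = np.flatnonzero(topo.peptide_heavy_mask(v.copy))
        lip_heavy = np.flatnonzero(topo.lipid_heavy_mask)
        lip_mol_heavy = topo.molecule_id[lip_heavy]
        # vectorized cos^2 over all frames
        vec = v.coords[:, hi, :] - v.coords[:, ci, :]
        cos2 = (vec[..., 2] ** 2) / np.sum(vec ** 2, axis=-1)
        scd_samples = 0.5 * (3.0 * cos2 - 1.0)        # (F, n_CH)
        if contact_split:
            in_contact = np.zeros(scd_samples.shape, bool)
            for f in range(v.n_frames):
                pairs = _pairs_within(v.coords[f][pep_heavy],
                                      v.coords[f][lip_heavy], cutoff,
                                      v.box[f][:2])
                mols = (np.unique(lip_mol_heavy[pairs[:, 1]])
                        if len(pairs) else np.empty(0, int))
                in_contact[f] = np.isin(mol, mols)
            prof = np.full((2, len(carbons)), np.nan)
            for s_idx, m in enumerate((~in_contact, in_contact)):
                for k, p in enumerate(carbons):
                    sel = m & (pos[None] == p)
                    if sel.any():
                        prof[s_idx, k] = -scd_samples[sel].mean()
        else:
            prof = np.empty((1, len(carbons)))
            for k, p in enumerate(carbons):
                prof[0, k] = -scd_samples[:, pos == p].mean()
        per_traj.setdefault(v.trajectory_id, []).append(prof)
    traj_means = np.array([np.nanmean(m, axis=0)
                           for m in per_traj.values()])
    mean = np.nanmean(traj_means, axis=0)
    n = len(traj_means)
    se = (np.nanstd(traj_means, axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.full_like(mean, np.nan))
    if contact_split:
        return OrderParameterProfile(
            carbons=carbons, minus_scd=mean[0], minus_scd_contact=mean[1],
            se=se[0], se_contact=se[1], n_trajectories=n)
    return OrderParameterProfile(
        carbons=carbons, minus_scd=mean[0], minus_scd_contact=None,
        se=se[0], se_contact=None, n_trajectories=n)
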