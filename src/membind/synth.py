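"""Synthetic peptide + bilayer trajectory generator with known ground truth.

Emulates a two-leaflet DMPC-like bilayer (49 lipids per leaflet on a jittered
lattice, phosphorus planes near |z| = 17.4 A), a 13-residue indolicidin-like
peptide per leaflet at reduced resolution (backbone N, CA, C, O plus a
side-chain centroid pseudo-atom sized by residue), a water slab of single-bead
pseudo-molecules, and chloride counterions.  Every planted feature -- residue
depth-state mixtures, pose templates, lipid coordination, hydrogen-bond
rates, chain-tilt order, a lateral density depression and a thickness dimple
-- is recorded exactly as sampled in a :class:`GroundTruth` object so that
every downstream estimator can be tested for parameter recovery.

This is not molecular dynamics: there are no energies and no Boltzmann
sampling.  Frames are independent draws from a stated noise model, which is
exactly what makes closed-form recovery checks possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .core import (G2, LEAFLET_LOWER, LEAFLET_UPPER, ROLE_ION, ROLE_LIPID,
                   ROLE_PEPTIDE, ROLE_WATER, IL_SEQUENCE, IL_CHARGE,
                   MolecularTopology, Trajectory, TrajectorySet,
                   assign_lipid_groups, atom_mass, guess_element,
                   SIDECHAIN_MASS)

TETRAHEDRAL_HALF = np.deg2rad(109.47122 / 2.0)
CH_BOND = 1.09
CC_RISE = 1.27  # projected C-C spacing along an all-trans chain axis

# head-group / glycerol / sn-1 heavy-atom offsets relative to P, upper leaflet
_HEAD_OFFSETS = {
    "N": (0.8, 0.4, 1.8), "C12": (1.6, -0.4, 2.4),
    "O11": (1.1, 0.6, 0.4), "O12": (-1.1, -0.6, 0.4),
    "C1": (0.3, -0.9, -2.2), "C2": (-0.4, 0.5, -3.0), "C3": (0.9, 0.6, -3.6),
    "C31": (1.3, 0.9, -5.0), "C32": (1.3, 0.9, -6.3),
    "C33": (1.3, 0.9, -7.6), "C34": (1.3, 0.9, -8.9),
}
_SN2_START = np.array([-1.0, -0.5, -4.6])  # C21 offset from P
_SN2_CARBONS = [f"C2{i}" for i in range(1, 15)]          # C21..C214
_SN2_H = {f"C2{i}": (f"H{i}R", f"H{i}S") for i in range(2, 15)}

LIPID_ATOM_NAMES = (["P"] + list(_HEAD_OFFSETS) + _SN2_CARBONS
                    + [h for c in _SN2_CARBONS[1:] for h in _SN2_H[c]])
LIPID_O11_OFFSET = np.array(_HEAD_OFFSETS["O11"])

# depth-state index convention
INSERTED, SURFACE, UNBOUND = 0, 1, 2
STATE_NAMES = ["inserted", "surface", "unbound"]


# ---------------------------------------------------------------------------
# chain-tilt model: density of cos(beta) proportional to exp(kappa cos(beta))
# on [0, 1]; closed forms used as the ground-truth S_CD oracle
# ---------------------------------------------------------------------------

def sample_tilt_cos(kappa: float, size, rng: np.random.Generator):
    """Sample cos(beta) with density prop. to exp(kappa*c) on [0, 1]."""
    if np.isinf(kappa):
        return np.ones(size)
    u = rng.random(size)
    if kappa == 0.0:
        return u
    return np.log1p(u * np.expm1(kappa)) / kappa


def expected_cos2_tilt(kappa: float) -> float:
    """E[cos^2 beta] under the exp(kappa c) tilt density on [0, 1]."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0.0:
        return 1.0 / 3.0
    ek = np.exp(kappa)
    return (ek * (kappa ** 2 - 2 * kappa + 2) - 2) / (kappa ** 2 * (ek - 1))


def expected_scd(kappa: float) -> float:
    """Closed-form S_CD for C-H bonds azimuthally uniform about a chain
    director tilted by beta from the bilayer normal: (1 - 3 E[cos^2 beta])/4.
    """
    return (1.0 - 3.0 * expected_cos2_tilt(kappa)) / 4.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_state_weights() -> np.ndarray:
    """Per-residue (P_inserted, P_surface, P_unbound) defaults.

    Emulates a C-terminally anchored binding profile: N-terminal residues
    favor the unbound state when not inserted, C-terminal residues the
    surface state, and residue 5 (Lys) is the least inserted.
    """
    w = np.tile([0.55, 0.15, 0.30], (13, 1))
    w[8:] = [0.60, 0.30, 0.10]
    w[4] = [0.40, 0.20, 0.40]
    return w


def default_turn_probabilities() -> np.ndarray:
    """Per-residue turn probabilities for the secondary-structure emitter."""
    p = np.full(13, 0.10)
    p[2:6] = 0.35   # interior residues 3-6
    p[8] = 0.30     # residue 9
    return p


@dataclass
class PoseTemplate:
    """A peptide pose: lateral CA arc plus a per-residue depth offset
    profile (A relative to z_P, used when ``depth_mode='template'``)."""

    name: str
    ca_xy: np.ndarray                 # (13, 2)
    depth_offsets: np.ndarray         # (13,)
    occupancy: float


@dataclass
class PlantedContact:
    """A lipid planted to coordinate one residue (or a tandem pair).

    Each frame the contact fires with probability ``rate``; fired frames
    place the lipid's O11 phosphate oxygen within heavy-atom contact range
    of the residue side-chain centroid, with hydrogen-bond geometry
    (D-A < 3.5 A, angle DHA ~ 180 deg) at probability ``hbond_rate``.
    """

    residue: int                      # 1-based
    partner_residue: int | None = None
    group: int = G2
    rate: float = 0.9
    hbond_rate: float = 0.0


def default_planted_contacts() -> list[PlantedContact]:
    return [
        PlantedContact(residue=1, rate=0.90, hbond_rate=0.37),
        PlantedContact(residue=5, rate=0.85, hbond_rate=0.46),
        PlantedContact(residue=12, rate=0.90, hbond_rate=0.61),
        PlantedContact(residue=13, rate=0.90, hbond_rate=0.66),
        PlantedContact(residue=12, partner_residue=13, rate=0.70,
                       hbond_rate=0.30),
        PlantedContact(residue=12, partner_residue=13, rate=0.60,
                       hbond_rate=0.30),
    ]


@dataclass
class SyntheticConfig:
    lipids_per_leaflet: int = 49
    frames: int = 500
    n_trajectories: int = 6
    seed: int = 0
    environment: str = "bilayer"            # "bilayer" or "water"
    box: tuple = (56.6, 56.6, 90.0)
    z_P_target: float = 17.4
    z_P_sd: float = 0.8                     # per-lipid phosphorus z spread
    jitter_sd: float = 0.8                  # per-frame lateral lipid jitter
    # residue depth-state mixture (offsets relative to z_P, A)
    state_weights: np.ndarray = field(default_factory=default_state_weights)
    depth_means: tuple = (-5.0, 3.0, 10.0)
    depth_sds: tuple = (2.0, 1.5, 2.5)
    surface_margin: float = 6.5
    unbound_limit: float = 30.0             # truncation of the unbound tail
    depth_mode: str = "mixture"             # "mixture" or "template"
    # pose model
    pose_templates: list = None
    pose_noise_sd: float = 0.4
    # chain order
    chain_tilt_concentration: float = 2.7   # bulk lipids
    contact_tilt_concentration: float = 2.3 # lipids in the binding footprint
    perturb_footprint: bool = True
    r_c: float = 13.0
    # bilayer response
    depression_fraction: float = 0.21
    dimple_depth: float = 11.9
    # solvent
    water_slab_density: float = 0.0334      # beads / A^3
    water_onset: float = 18.0
    # planted coordination
    contact_enrichment: list = None
    # secondary structure emission
    turn_probabilities: np.ndarray = field(
        default_factory=default_turn_probabilities)
    beta_turn_rate: float = 0.60
    gamma_turn_rate: float = 0.12

    def __post_init__(self):
        self.state_weights = np.asarray(self.state_weights, float)
        if self.pose_templates is None:
            self.pose_templates = default_pose_templates()
        if self.contact_enrichment is None:
            self.contact_enrichment = (default_planted_contacts()
                                       if self.environment == "bilayer" else [])
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if not np.allclose(self.state_weights.sum(axis=1), 1.0):
            raise ValueError("state mixture weights must sum to 1 per residue")
        for sd in (*self.depth_sds, self.jitter_sd, self.pose_noise_sd,
                   self.z_P_sd):
            if sd < 0:
                raise ValueError("all standard deviations must be >= 0")
        if self.environment not in ("bilayer", "water"):
            raise ValueError("environment must be 'bilayer' or 'water'")


def default_pose_templates() -> list[PoseTemplate]:
    """Three laterally distinct poses: open arc, hairpin, compact coil."""
    i = np.arange(13)
    # open arc, radius 9 A over ~180 deg
    a = np.pi * i / 12.0
    arc = np.stack([9.0 * np.cos(a), 9.0 * np.sin(a)], axis=1)
    # hairpin: two antiparallel legs 5.5 A apart
    leg = np.where(i < 7, i, 12 - i) * 3.4
    side = np.where(i < 7, 0.0, 5.5)
    hairpin = np.stack([leg - 10.0, side], axis=1)
    # compact coil, radius 5.5 A over ~300 deg
    b = 5.0 * np.pi / 3.0 * i / 12.0
    coil = np.stack([5.5 * np.cos(b), 5.5 * np.sin(b)], axis=1)
    depths = [
        np.full(13, -4.0),                       # inserted pose
        np.concatenate([np.full(7, 4.0), np.full(6, 0.5)]),  # part-surface
        np.full(13, 8.0),                        # shallow/unbound pose
    ]
    out = []
    for name, xy, d, occ in zip(["arc", "hairpin", "coil"],
                                [arc, hairpin, coil], depths,
                                [0.45, 0.35, 0.20]):
        out.append(PoseTemplate(name=name, ca_xy=xy - xy.mean(axis=0),
                                depth_offsets=d, occupancy=occ))
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    state_weights: np.ndarray
    state_counts: np.ndarray          # (n_traj, 13, 3)
    template_occupancies: np.ndarray
    template_counts: np.ndarray       # (n_traj, n_templates)
    template_ids: list                # per trajectory, (frames,) int
    kappa_bulk: float
    kappa_contact: float
    expected_scd_bulk: float
    expected_scd_contact: float
    planted_contacts: list
    planted_fire_counts: np.ndarray
    expected_region_density_ratio: float
    dimple_depth: float
    depression_fraction: float
    peptide_charge_per_copy: int
    counterions_per_peptide: int
    ss_turn_probabilities: np.ndarray | None = None
    ss_turn_counts: dict | None = None

    def to_json(self, path):
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            return x
        d = {}
        for k, v in asdict(self).items():
            if k == "planted_contacts":
                d[k] = v
            elif isinstance(v, list):
                d[k] = [conv(e) for e in v]
            else:
                d[k] = conv(v)
        Path(path).write_text(json.dumps(d, indent=1, default=conv))


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def _peptide_atom_plan():
    """Per-residue atom kinds for the reduced peptide model."""
    plan = []
    for i, res in enumerate(IL_SEQUENCE):
        kinds = ["N"]
        if res != "PRO":
            kinds.append("HN")
        kinds += ["CA", "C", "O", "SC"]
        if res in ("LYS", "ARG"):
            kinds.append("HSC")
        plan.append((res, kinds))
    return plan


def build_topology(config: SyntheticConfig):
    """Create the MolecularTopology plus index bookkeeping for assembly."""
    names, resnames, resid_local, mol_id, role, copy_arr = [], [], [], [], [], []
    leaflet = []
    plan = _peptide_atom_plan()
    mol = 0
    copies = ([LEAFLET_UPPER, LEAFLET_LOWER]
              if config.environment == "bilayer" else [LEAFLET_UPPER])
    pep_slices = {}
    for cp in copies:
        start = len(names)
        for ri, (res, kinds) in enumerate(plan, start=1):
            for k in kinds:
                names.append(k)
                resnames.append(res)
                resid_local.append(ri)
                mol_id.append(mol)
                role.append(ROLE_PEPTIDE)
                copy_arr.append(cp)
                leaflet.append(0)
        pep_slices[cp] = slice(start, len(names))
        mol += 1
    lipid_slices = {}
    if config.environment == "bilayer":
        for lf in (LEAFLET_UPPER, LEAFLET_LOWER):
            start = len(names)
            for li in range(config.lipids_per_leaflet):
                for k in LIPID_ATOM_NAMES:
                    names.append(k)
                    resnames.append("DMPC")
                    resid_local.append(1)
                    mol_id.append(mol)
                    role.append(ROLE_LIPID)
                    copy_arr.append(0)
                    leaflet.append(lf)
                mol += 1
            lipid_slices[lf] = slice(start, len(names))
    # waters
    n_w = _water_count(config)
    w_start = len(names)
    for wi in range(n_w):
        names.append("OH2")
        resnames.append("TIP3")
        resid_local.append(1)
        mol_id.append(mol)
        role.append(ROLE_WATER)
        copy_arr.append(0)
        leaflet.append(0)
        mol += 1
    water_slice = slice(w_start, len(names))
    n_ions = IL_CHARGE * len(copies)
    i_start = len(names)
    for ii in range(n_ions):
        names.append("CLA")
        resnames.append("CLA")
        resid_local.append(1)
        mol_id.append(mol)
        role.append(ROLE_ION)
        copy_arr.append(0)
        leaflet.append(0)
        mol += 1
    ion_slice = slice(i_start, len(names))

    names = np.array(names, dtype="U6")
    resnames = np.array(resnames, dtype="U6")
    role = np.array(role, np.int8)
    heavy = np.array([guess_element(n, r) != "H"
                      for n, r in zip(names, resnames)])
    masses = np.array([atom_mass(n, r) for n, r in zip(names, resnames)])
    groups = assign_lipid_groups(names, resnames, role, heavy)
    mol_id = np.array(mol_id, np.int64)
    resid_local = np.array(resid_local, np.int64)
    # global residue index
    residue_index = np.zeros(len(names), np.int64)
    counter, last = 0, None
    for i in range(len(names)):
        key = (mol_id[i], resid_local[i])
        if key != last:
            counter += 1
            last = key
        residue_index[i] = counter
    topo = MolecularTopology(
        atom_names=names, resnames=resnames, residue_index=residue_index,
        resid_local=resid_local, molecule_id=mol_id, role=role,
        lipid_group=groups, leaflet=np.array(leaflet, np.int8),
        peptide_copy=np.array(copy_arr, np.int8), masses=masses, heavy=heavy)
    meta = {"pep_slices": pep_slices, "lipid_slices": lipid_slices,
            "water_slice": water_slice, "ion_slice": ion_slice,
            "n_waters": n_w, "plan": plan}
    return topo, meta


def _water_count(config: SyntheticConfig) -> int:
    lx, ly, lz = config.box
    if config.environment == "water":
        return int(round(config.water_slab_density * lx * ly * lz))
    z_top = lz / 2.0 - 2.0
    v_flat = lx * ly * max(z_top - config.water_onset, 0.0)
    v_dimple = config.dimple_depth * np.pi * config.r_c ** 2 / 2.0
    per_side = config.water_slab_density * (v_flat + v_dimple / 1.0)
    return int(round(2 * per_side))


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _lattice_sites(config) -> np.ndarray:
    n_side = int(round(np.sqrt(config.lipids_per_leaflet)))
    if n_side * n_side != config.lipids_per_leaflet:
        raise ValueError("lipids_per_leaflet must be a square number")
    a = config.box[0] / n_side
    g = (np.arange(n_side) - (n_side - 1) / 2.0) * a
    xx, yy = np.meshgrid(g, g, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def _min_image(d, lx, ly):
    d = d.copy()
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def _perp_basis(d):
    """Orthonormal (e1, e2) perpendicular to unit vectors d (..., 3)."""
    z = np.zeros_like(d)
    z[..., 2] = 1.0
    c = np.cross(d, z)
    n = np.linalg.norm(c, axis=-1, keepdims=True)
    fallback = np.zeros_like(d)
    fallback[..., 0] = 1.0
    e1 = np.where(n > 1e-8, c / np.where(n > 0, n, 1.0), fallback)
    e2 = np.cross(d, e1)
    return e1, e2


def _sample_depth_offsets(states, config, rng):
    """Truncated-normal depth offsets (relative to z_P) per sampled state."""
    off = np.zeros(states.shape)
    bounds = [(-np.inf, 0.0), (0.0, config.surface_margin),
              (config.surface_margin, config.unbound_limit)]
    for s, (lo, hi) in enumerate(bounds):
        m = states == s
        if not m.any():
            continue
        mu, sd = config.depth_means[s], config.depth_sds[s]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        off[m] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=int(m.sum()),
                               random_state=rng)
    return off


def _place_peptide(config, tpl_ids, states_off, center, s, rng, z_P_final,
                   meta, coords, pep_slice):
    """Fill peptide atom coordinates for one copy (vectorized per template).

    ``states_off`` are side-chain z offsets relative to z_P; ``s`` = +1/-1
    mirrors the copy into the lower leaflet; ``z_P_final`` is the per-frame
    phosphorus-plane height the offsets refer to (unsigned).
    """
    F = len(tpl_ids)
    plan = meta["plan"]
    templates = config.pose_templates
    ca_xy = np.empty((F, 13, 2))
    for t, tpl in enumerate(templates):
        m = tpl_ids == t
        if m.any():
            ca_xy[m] = tpl.ca_xy[None]
    ca_xy = ca_xy + rng.normal(0.0, config.pose_noise_sd, size=ca_xy.shape)
    ca_xy += np.asarray(center)[None, None, :]
    # tangents and outward normals
    t_vec = np.empty_like(ca_xy)
    t_vec[:, 1:-1] = ca_xy[:, 2:] - ca_xy[:, :-2]
    t_vec[:, 0] = ca_xy[:, 1] - ca_xy[:, 0]
    t_vec[:, -1] = ca_xy[:, -1] - ca_xy[:, -2]
    t_vec /= np.linalg.norm(t_vec, axis=-1, keepdims=True)
    n_vec = np.stack([-t_vec[..., 1], t_vec[..., 0]], axis=-1)
    z_sc = s * (z_P_final[:, None] + states_off)       # (F, 13) signed
    z_bb = z_sc + s * 2.0
    sc_len = np.array([SIDECHAIN_MASS.get(r, 50.0) ** (1 / 3.0)
                       for r, _ in plan])  # ~1.6-5 A reach by residue bulk
    idx = pep_slice.start
    for ri, (res, kinds) in enumerate(plan):
        ca = ca_xy[:, ri]
        t = t_vec[:, ri]
        n = n_vec[:, ri]
        pos = {
            "N": np.concatenate([ca - 1.2 * t, z_bb[:, ri:ri + 1]], axis=1),
            "CA": np.concatenate([ca, z_bb[:, ri:ri + 1]], axis=1),
            "C": np.concatenate([ca + 1.2 * t, z_bb[:, ri:ri + 1]], axis=1),
            "O": np.concatenate([ca + 1.2 * t + 0.6 * n,
                                 z_bb[:, ri:ri + 1] + s * 0.5], axis=1),
            "SC": np.concatenate([ca + sc_len[ri] * 0.8 * n,
                                  z_sc[:, ri:ri + 1]], axis=1),
        }
        pos["HN"] = pos["N"] + np.array([0.0, 0.0, -1.0]) * s
        pos["HSC"] = pos["SC"] + np.array([0.0, 0.0, -1.0]) * s
        for k in kinds:
            coords[:, idx] = pos[k]
            idx += 1
    return ca_xy.mean(axis=1)  # per-frame lateral peptide center


def _generate_one(config: SyntheticConfig, topo, meta, rng, truth_acc):
    F = config.frames
    lx, ly, lz = config.box
    N = topo.n_atoms
    coords = np.empty((F, N, 3), np.float32)
    box = np.tile(np.array([lx, ly, lz]), (F, 1))

    copies = topo.peptide_copies()
    # pose template ids (shared by both copies? no: independent samples)
    occ = np.array([t.occupancy for t in config.pose_templates])
    occ = occ / occ.sum()

    if config.environment == "water":
        tpl = rng.choice(len(occ), size=F, p=occ)
        z_off = rng.normal(0.0, 2.0, size=(F, 13))
        zeros = np.zeros(F)
        _place_peptide(config, tpl, z_off, (0.0, 0.0), 1, rng, zeros,
                       meta, coords, meta["pep_slices"][LEAFLET_UPPER])
        truth_acc["template_ids"].append(tpl)
        ws = meta["water_slice"]
        n_w = ws.stop - ws.start
        coords[:, ws, 0] = rng.uniform(-lx / 2, lx / 2, (F, n_w))
        coords[:, ws, 1] = rng.uniform(-ly / 2, ly / 2, (F, n_w))
        coords[:, ws, 2] = rng.uniform(-lz / 2, lz / 2, (F, n_w))
        isl = meta["ion_slice"]
        n_i = isl.stop - isl.start
        coords[:, isl] = rng.uniform(-lx / 2, lx / 2, (F, n_i, 3))
        return Trajectory(coords=coords, box=box), None

    sites = _lattice_sites(config)
    n_l = config.lipids_per_leaflet
    # maximal lateral separation so each leaflet's field is unperturbed
    # around the opposing peptide
    pep_centers = {LEAFLET_UPPER: np.array([0.0, 0.0]),
                   LEAFLET_LOWER: np.array([lx / 2.0, ly / 2.0])}
    # planted slots: per leaflet, lipids from lattice shells near the
    # footprint boundary (home sites ~11-16 A out; fired frames pull them
    # under the designated residue)
    planted = config.contact_enrichment
    site_r = np.linalg.norm(sites, axis=1)
    order = np.argsort(np.abs(site_r - 11.0), kind="stable")
    slot_sites = order[:len(planted)]

    kb, kc = config.chain_tilt_concentration, config.contact_tilt_concentration

    for lf in (LEAFLET_UPPER, LEAFLET_LOWER):
        s = 1.0 if lf == LEAFLET_UPPER else -1.0
        center = pep_centers[lf]
        lsl = meta["lipid_slices"][lf]
        # --- lipid lateral positions -------------------------------------
        xy = sites[None] + rng.normal(0, config.jitter_sd, (F, n_l, 2))
        xy += center[None, None, :]
        d_cen = np.linalg.norm(_min_image(xy - center[None, None, :], lx, ly),
                               axis=-1)
        near = d_cen < config.r_c
        exempt = np.zeros(n_l, bool)
        exempt[slot_sites] = True
        disp = near & (~exempt[None]) & (
            rng.random((F, n_l)) < config.depression_fraction)
        if disp.any():
            u = _min_image(xy - center[None, None, :], lx, ly)
            r = np.linalg.norm(u, axis=-1)
            r_safe = np.where(r > 1e-9, r, 1.0)
            new_r = config.r_c + rng.uniform(0, 4.0, (F, n_l))
            scale = np.where(disp, new_r / r_safe, 1.0)
            xy = center[None, None, :] + u * scale[..., None]
            d_cen = np.linalg.norm(
                _min_image(xy - center[None, None, :], lx, ly), axis=-1)
        # --- phosphorus z, dimple ----------------------------------------
        pz = config.z_P_target + rng.normal(0, config.z_P_sd, (F, n_l))
        dimple = config.dimple_depth * np.clip(
            1.0 - (d_cen / config.r_c) ** 2, 0.0, None)
        pz = pz - dimple
        z_P_pre = pz.mean(axis=1)
        # --- peptide depths and fixed-point z_P --------------------------
        states = np.empty((F, 13), np.int64)
        for ri in range(13):
            states[:, ri] = rng.choice(3, size=F, p=config.state_weights[ri])
        if config.depth_mode == "mixture":
            off = _sample_depth_offsets(states, config, rng)
        else:
            off = np.empty((F, 13))
            tpl_pre = truth_acc.get("_tpl_" + str(lf))
            for t, tplt in enumerate(config.pose_templates):
                m = tpl_pre == t
                off[m] = tplt.depth_offsets[None]
            off += rng.normal(0, 0.5, off.shape)
        tpl_ids = truth_acc.get("_tpl_" + str(lf))
        # planted firing
        fired = np.zeros((F, len(planted)), bool)
        hb = np.zeros((F, len(planted)), bool)
        for j, pc in enumerate(planted):
            fired[:, j] = rng.random(F) < pc.rate
            hb[:, j] = fired[:, j] & (rng.random(F) < pc.hbond_rate)
        # fixed point: z_P after planted translations (O11 placed relative
        # to the side chain whose z refers to the final z_P)
        g = np.zeros((F, len(planted)))
        for j, pc in enumerate(planted):
            if pc.partner_residue is None:
                oi = off[:, pc.residue - 1]
                g[:, j] = np.where(hb[:, j], oi - 3.2 - 0.4, oi - 1.0 - 0.4)
            else:
                oi = 0.5 * (off[:, pc.residue - 1]
                            + off[:, pc.partner_residue - 1])
                g[:, j] = oi - 2.5 - 0.4
        m_fired = fired.sum(axis=1)
        p_old = pz[:, slot_sites]                      # (F, n_slots)
        num = z_P_pre + (np.where(fired, g - p_old, 0.0).sum(axis=1)) / n_l
        z_P_final = num / (1.0 - m_fired / n_l)
        # --- place peptide ------------------------------------------------
        pep_center_xy = _place_peptide(
            config, tpl_ids, off, center, s, rng, z_P_final, meta, coords,
            meta["pep_slices"][lf])
        # --- planted lipid translations ----------------------------------
        sc_idx = topo.sidechain_indices(lf)
        for j, pc in enumerate(planted):
            li = slot_sites[j]
            fj = fired[:, j]
            if not fj.any():
                continue
            sc_a = coords[fj, sc_idx[pc.residue - 1]].astype(np.float64)
            if pc.partner_residue is None:
                tgt = sc_a.copy()
                dz = np.where(hb[fj, j], 3.2, 1.0)
                dx = np.where(hb[fj, j], 0.0, 3.8)
                tgt[:, 0] += dx
                tgt[:, 2] -= s * dz
            else:
                sc_b = coords[fj, sc_idx[pc.partner_residue - 1]]
                tgt = 0.5 * (sc_a + sc_b)
                tgt[:, 2] -= s * 2.5
            # lipid P so that O11 lands on target
            pz[fj, li] = s * tgt[:, 2] - LIPID_O11_OFFSET[2]
            xy[fj, li] = tgt[:, :2] - LIPID_O11_OFFSET[:2]
        # --- chain tilt ---------------------------------------------------
        kappa_sel = np.where(config.perturb_footprint & (d_cen < config.r_c),
                             kc, kb)
        c = np.empty((F, n_l))
        for kv in np.unique(kappa_sel):
            m = kappa_sel == kv
            c[m] = sample_tilt_cos(kv, int(m.sum()), rng)
        beta = np.arccos(np.clip(c, -1, 1))
        phi = rng.uniform(0, 2 * np.pi, (F, n_l))
        director = np.stack([np.sin(beta) * np.cos(phi),
                             np.sin(beta) * np.sin(phi),
                             -s * c], axis=-1)
        # --- assemble lipid atoms ----------------------------------------
        P = np.concatenate([xy, (s * pz)[..., None]], axis=-1)  # (F,n_l,3)
        base = lsl.start
        n_at = len(LIPID_ATOM_NAMES)
        name_pos = {n: i for i, n in enumerate(LIPID_ATOM_NAMES)}
        lip = np.empty((F, n_l, n_at, 3))
        for nm, offv in _HEAD_OFFSETS.items():
            o = np.array(offv) * np.array([1.0, 1.0, s])
            lip[:, :, name_pos[nm]] = P + o
        lip[:, :, name_pos["P"]] = P
        start = P + _SN2_START * np.array([1.0, 1.0, s])
        for k, cn in enumerate(_SN2_CARBONS):
            lip[:, :, name_pos[cn]] = start + director * (CC_RISE * k)
        e1, e2 = _perp_basis(director)
        psi = rng.uniform(0, 2 * np.pi, (F, n_l))
        for cn in _SN2_CARBONS[1:]:
            cpos = lip[:, :, name_pos[cn]]
            for hname, sign in zip(_SN2_H[cn], (1.0, -1.0)):
                ang = psi + sign * TETRAHEDRAL_HALF
                hvec = (np.cos(ang)[..., None] * e1
                        + np.sin(ang)[..., None] * e2)
                lip[:, :, name_pos[hname]] = cpos + CH_BOND * hvec
        coords[:, lsl] = lip.reshape(F, n_l * n_at, 3)
        # --- per-leaflet truth --------------------------------------------
        truth_acc["state_counts"] += np.stack(
            [np.sum(states == si, axis=0) for si in range(3)], axis=1)
        truth_acc["fire_counts"] += fired.sum(axis=0)

    # --- waters (rejection-sampled into the dimple-following slabs) -------
    ws = meta["water_slice"]
    n_w = ws.stop - ws.start
    n_half = n_w // 2
    z_top = lz / 2.0 - 2.0
    for side, (lf, cnt) in enumerate([(LEAFLET_UPPER, n_half),
                                      (LEAFLET_LOWER, n_w - n_half)]):
        s = 1.0 if lf == LEAFLET_UPPER else -1.0
        center = pep_centers[lf]
        need = F * cnt
        got_xy = np.empty((0, 2))
        got_z = np.empty(0)
        z_min_glob = config.water_onset - config.dimple_depth
        while len(got_z) < need:
            batch = int((need - len(got_z)) * 1.6) + 64
            x = rng.uniform(-lx / 2, lx / 2, batch)
            y = rng.uniform(-ly / 2, ly / 2, batch)
            z = rng.uniform(z_min_glob, z_top, batch)
            d = np.linalg.norm(_min_image(
                np.stack([x, y], axis=1) - center[None], lx, ly), axis=1)
            onset = config.water_onset - config.dimple_depth * np.clip(
                1.0 - (d / config.r_c) ** 2, 0.0, None)
            keep = z >= onset
            got_xy = np.concatenate([got_xy, np.stack([x, y], 1)[keep]])
            got_z = np.concatenate([got_z, z[keep]])
        got_xy = got_xy[:need]
        got_z = got_z[:need] * s
        blk = slice(ws.start + (0 if side == 0 else n_half),
                    ws.start + (n_half if side == 0 else n_w))
        coords[:, blk, :2] = got_xy.reshape(F, cnt, 2)
        coords[:, blk, 2] = got_z.reshape(F, cnt)
    isl = meta["ion_slice"]
    n_i = isl.stop - isl.start
    coords[:, isl, 0] = rng.uniform(-lx / 2, lx / 2, (F, n_i))
    coords[:, isl, 1] = rng.uniform(-ly / 2, ly / 2, (F, n_i))
    half = rng.uniform(config.water_onset + 1, z_top, (F, n_i))
    sign = np.where(np.arange(n_i)[None, :] % 2 == 0, 1.0, -1.0)
    coords[:, isl, 2] = half * sign
    return Trajectory(coords=coords, box=box), None


def _expected_region_density_ratio(config: SyntheticConfig) -> float:
    """Expected near/away mean-density ratio of the peptide's leaflet.

    Valid for the no-dimple geometry: counts lipids by home region, moving
    a ``depression_fraction`` of unplanted near lipids into the first away
    annulus and fired planted lipids under the peptide.
    """
    sites = _lattice_sites(config)
    r = np.linalg.norm(sites, axis=1)
    r_max = config.box[0] / 2.0
    planted = config.contact_enrichment
    order = np.argsort(np.abs(r - 11.0), kind="stable")
    slot = set(order[:len(planted)].tolist())
    f = config.depression_fraction
    near = away = 0.0
    for i in range(len(sites)):
        if i in slot:
            j = order[:len(planted)].tolist().index(i)
            rate = planted[j].rate
            p_near = rate + (1 - rate) * (1.0 if r[i] < config.r_c else 0.0)
            near += p_near
            away += 1 - p_near
        elif r[i] < config.r_c:
            near += 1 - f
            away += f
        elif r[i] < r_max:
            away += 1.0
    a_near = np.pi * config.r_c ** 2
    a_away = np.pi * (r_max ** 2 - config.r_c ** 2)
    return (near / a_near) / (away / a_away)


def generate_trajectory(config: SyntheticConfig):
    """Generate the synthetic system.

    Returns ``(TrajectorySet, GroundTruth)``.  Deterministic given
    ``config.seed``: the same seed yields bit-identical coordinates.
    """
    topo, meta = build_topology(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_trajectories)
    n_tpl = len(config.pose_templates)
    occ = np.array([t.occupancy for t in config.pose_templates])
    occ = occ / occ.sum()
    truth_acc = {
        "state_counts": np.zeros((13, 3), np.int64),
        "fire_counts": np.zeros(len(config.contact_enrichment), np.int64),
        "template_ids": [],
    }
    state_counts = np.zeros((config.n_trajectories, 13, 3), np.int64)
    tpl_counts = np.zeros((config.n_trajectories, n_tpl), np.int64)
    trajectories = []
    for k in range(config.n_trajectories):
        rng = np.random.default_rng(children[k])
        per = {"state_counts": np.zeros((13, 3), np.int64),
               "fire_counts": truth_acc["fire_counts"],
               "template_ids": truth_acc["template_ids"]}
        # template ids per copy, sampled up-front so depth_mode="template"
        # can use them; both copies contribute structures
        if config.environment == "bilayer":
            for lf in (LEAFLET_UPPER, LEAFLET_LOWER):
                ids = rng.choice(n_tpl, size=config.frames, p=occ)
                per["_tpl_" + str(lf)] = ids
                tpl_counts[k] += np.bincount(ids, minlength=n_tpl)
            truth_acc["template_ids"].append(per["_tpl_" + str(LEAFLET_UPPER)])
        traj, _ = _generate_one(config, topo, meta, rng, per)
        traj.trajectory_id = k
        trajectories.append(traj)
        state_counts[k] = per["state_counts"]
        if config.environment == "water":
            tpl_counts[k] = np.bincount(per["template_ids"][-1],
                                        minlength=n_tpl)
    trajset = TrajectorySet(topology=topo, trajectories=trajectories)
    truth = GroundTruth(
        state_weights=config.state_weights.copy(),
        state_counts=state_counts,
        template_occupancies=occ,
        template_counts=tpl_counts,
        template_ids=truth_acc["template_ids"],
        kappa_bulk=config.chain_tilt_concentration,
        kappa_contact=config.contact_tilt_concentration,
        expected_scd_bulk=expected_scd(config.chain_tilt_concentration),
        expected_scd_contact=expected_scd(config.contact_tilt_concentration),
        planted_contacts=[asdict(p) for p in config.contact_enrichment],
        planted_fire_counts=truth_acc["fire_counts"],
        expected_region_density_ratio=(
            _expected_region_density_ratio(config)
            if config.environment == "bilayer" else float("nan")),
        dimple_depth=config.dimple_depth,
        depression_fraction=config.depression_fraction,
        peptide_charge_per_copy=IL_CHARGE,
        counterions_per_peptide=IL_CHARGE,
        ss_turn_probabilities=np.asarray(config.turn_probabilities, float),
    )
    return trajset, truth


# ---------------------------------------------------------------------------
# secondary-structure emission (STRIDE ASG dialect)
# ---------------------------------------------------------------------------

_TURN_BETA = "TurnIV"
_TURN_GAMMA = "GammaInv"


def emit_stride_like_assignments(config: SyntheticConfig, path,
                                 frames: int | None = None,
                                 seed: int | None = None):
    """Write per-frame {T, C} labels plus beta/gamma-turn records.

    The file uses the STRIDE ASG-record dialect (one ``REM  FRAME k`` block
    per frame) accepted by :func:`membind.peptide.parse_stride`.  Labels are
    sampled independently per residue per frame from
    ``config.turn_probabilities``; per-frame turn-record counts are Poisson
    with means ``beta_turn_rate`` / ``gamma_turn_rate``.

    Returns a dict with the planted label matrix and exact turn counts.
    """
    frames = frames if frames is not None else config.frames
    rng = np.random.default_rng(
        seed if seed is not None else config.seed + 777)
    p = np.asarray(config.turn_probabilities, float)
    labels = rng.random((frames, 13)) < p[None]
    n_beta = rng.poisson(config.beta_turn_rate, frames)
    n_gamma = rng.poisson(config.gamma_turn_rate, frames)
    lines = []
    for f in range(frames):
        lines.append(f"REM  FRAME {f + 1}")
        for ri, res in enumerate(IL_SEQUENCE):
            code = "T" if labels[f, ri] else "C"
            full = "Turn" if labels[f, ri] else "Coil"
            lines.append(
                f"ASG  {res:3s} A {ri + 1:4d} {ri + 1:4d}    {code}   "
                f"{full:11s}   360.00    360.00       0.0")
        for _ in range(int(n_beta[f])):
            i = int(rng.integers(1, 11))
            lines.append(f"LOC  {_TURN_BETA:12s} {IL_SEQUENCE[i - 1]:3s} "
                         f"{i:4d} A      {IL_SEQUENCE[i + 2]:3s} {i + 3:4d} A")
        for _ in range(int(n_gamma[f])):
            i = int(rng.integers(1, 12))
            lines.append(f"LOC  {_TURN_GAMMA:12s} {IL_SEQUENCE[i - 1]:3s} "
                         f"{i:4d} A      {IL_SEQUENCE[i + 1]:3s} {i + 2:4d} A")
    Path(path).write_text("\n".join(lines) + "\n")
    return {"labels": labels, "n_beta": n_beta, "n_gamma": n_gamma,
            "turn_probabilities": p}
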