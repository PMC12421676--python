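"""Data model for membrane-peptide trajectories.

Holds the molecular topology (roles, lipid structural groups G1-G5, leaflet
assignment), per-frame bilayer geometry (phosphorus planes, midplane), the
leaflet canonicalization that maps every analyzed peptide copy into a single
"upper leaflet" convention, and PDB/DCD/XTC readers and writers (backed by
MDAnalysis).

Coordinate conventions
----------------------
All coordinates are in Angstrom with an orthorhombic box; the bilayer normal
is the z axis.  After canonicalization the bilayer midplane sits at z = 0 and
the analyzed peptide's leaflet is mapped to positive z, so every reported
depth is a signed distance from the midplane.  The lateral minimum-image
convention applies in x, y only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("membind")

# molecule roles
ROLE_PEPTIDE = 1
ROLE_LIPID = 2
ROLE_WATER = 3
ROLE_ION = 4

ROLE_NAMES = {ROLE_PEPTIDE: "peptide", ROLE_LIPID: "lipid",
              ROLE_WATER: "water", ROLE_ION: "ion"}

# lipid structural groups (0 = none)
G1, G2, G3, G4, G5 = 1, 2, 3, 4, 5
GROUP_NAMES = {G1: "G1", G2: "G2", G3: "G3", G4: "G4", G5: "G5"}

LEAFLET_UPPER = 1
LEAFLET_LOWER = -1
LEAFLET_NONE = 0

#: CHARMM36 DMPC heavy-atom name -> structural group.  G1 choline, G2
#: phosphate, G3 glycerol backbone, G4 sn-1 myristoyl (C3x), G5 sn-2
#: myristoyl (C2x).  Ester oxygens and carbonyl carbons are grouped with
#: their chains.  Users may supply their own table via ``load_group_map``.
DMPC_GROUP_MAP: dict[str, int] = {}
for _n in ["N", "C11", "C12", "C13", "C14", "C15"]:
    DMPC_GROUP_MAP[_n] = G1
for _n in ["P", "O11", "O12", "O13", "O14"]:
    DMPC_GROUP_MAP[_n] = G2
for _n in ["C1", "C2", "C3"]:
    DMPC_GROUP_MAP[_n] = G3
DMPC_GROUP_MAP.update({"O31": G4, "O32": G4})
DMPC_GROUP_MAP.update({"O21": G5, "O22": G5})
for _i in range(1, 15):
    DMPC_GROUP_MAP[f"C3{_i}"] = G4
    DMPC_GROUP_MAP[f"C2{_i}"] = G5

PEPTIDE_RESNAMES = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
                    "HIS", "HSD", "HSE", "ILE", "LEU", "LYS", "MET", "PHE",
                    "PRO", "SER", "THR", "TRP", "TYR", "VAL"}
LIPID_RESNAMES = {"DMPC"}
WATER_RESNAMES = {"TIP3", "HOH", "WAT", "SOL", "TIP"}
ION_RESNAMES = {"CLA", "CL", "SOD", "NA", "POT", "K"}

#: Indolicidin sequence, ILPWKWPWWPWRR (amidated C-terminus, +4 charge).
IL_SEQUENCE = ["ILE", "LEU", "PRO", "TRP", "LYS", "TRP", "PRO",
               "TRP", "TRP", "PRO", "TRP", "ARG", "ARG"]
IL_CHARGE = 4

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
         "P": 30.974, "S": 32.06, "CL": 35.45, "NA": 22.990, "K": 39.098}

# approximate side-chain heavy mass for the reduced single-bead side chain
SIDECHAIN_MASS = {"ILE": 57.1, "LEU": 57.1, "PRO": 42.1, "TRP": 130.2,
                  "LYS": 73.1, "ARG": 101.1, "GLY": 1.0, "ALA": 15.0}


def guess_element(name: str, resname: str = "") -> str:
    """Guess the chemical element from an atom name.

    Pseudo-atoms of the reduced peptide model (``SC`` side-chain centroid,
    ``HSC`` its polar hydrogen) are handled explicitly.
    """
    name = name.strip().upper()
    if name in ("CLA", "CL"):
        return "CL"
    if name in ("SOD",):
        return "NA"
    if name == "SC":
        return "C"
    if name in ("HSC", "HN", "OH2"[:0]):
        return "H"
    if name == "OH2":
        return "O"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0]


def atom_mass(name: str, resname: str = "") -> float:
    if name.strip().upper() == "SC":
        return SIDECHAIN_MASS.get(resname.strip().upper(), 50.0)
    return _MASS.get(guess_element(name, resname), 12.011)


def load_group_map(path: str | Path | None = None) -> dict[str, int]:
    """Return the lipid atom-name -> G1..G5 table.

    ``path`` may point to a two-column CSV ``atom_name,group`` with group in
    {G1..G5}; without it the shipped CHARMM36 DMPC table is returned.
    """
    if path is None:
        return dict(DMPC_GROUP_MAP)
    table = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("atom"):
            continue
        name, grp = [f.strip() for f in line.split(",")[:2]]
        table[name.upper()] = {"G1": G1, "G2": G2, "G3": G3,
                               "G4": G4, "G5": G5}[grp.upper()]
    return table


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class MolecularTopology:
    """Per-atom annotation of a peptide + bilayer + solvent system.

    ``residue_index`` is a global 1-based residue counter; ``resid_local``
    restarts inside each molecule (1..13 for each peptide copy).
    ``molecule_id`` identifies a molecule (one peptide copy, one lipid, one
    water bead, one ion).
    """

    atom_names: np.ndarray
    resnames: np.ndarray
    residue_index: np.ndarray
    resid_local: np.ndarray
    molecule_id: np.ndarray
    role: np.ndarray
    lipid_group: np.ndarray
    leaflet: np.ndarray
    peptide_copy: np.ndarray  # +1 upper copy, -1 lower copy, 0 none
    masses: np.ndarray
    heavy: np.ndarray
    is_donor: np.ndarray = field(default=None)
    donor_h: np.ndarray = field(default=None)
    is_acceptor: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.is_donor is None:
            self._tag_donors_acceptors()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    # -- convenience masks -------------------------------------------------
    def peptide_mask(self, copy: int | None = None) -> np.ndarray:
        m = self.role == ROLE_PEPTIDE
        if copy is not None:
            m &= self.peptide_copy == copy
        return m

    def peptide_heavy_mask(self, copy: int | None = None) -> np.ndarray:
        return self.peptide_mask(copy) & self.heavy

    @property
    def lipid_heavy_mask(self) -> np.ndarray:
        return (self.role == ROLE_LIPID) & self.heavy

    @property
    def phosphorus_mask(self) -> np.ndarray:
        return (self.role == ROLE_LIPID) & (self.atom_names == "P")

    def peptide_copies(self) -> list[int]:
        return sorted(set(self.peptide_copy[self.role == ROLE_PEPTIDE]))

    def residue_atoms(self, copy: int) -> list[np.ndarray]:
        """Atom index arrays for residues 1..n of one peptide copy."""
        out = []
        m = self.peptide_mask(copy)
        for r in np.unique(self.resid_local[m]):
            out.append(np.flatnonzero(m & (self.resid_local == r)))
        return out

    def sidechain_indices(self, copy: int) -> np.ndarray:
        """Index of the side-chain centroid pseudo-atom per residue.

        Residues lacking a side chain fall back to the C-alpha atom.
        """
        idx = []
        for atoms in self.residue_atoms(copy):
            names = self.atom_names[atoms]
            sc = atoms[names == "SC"]
            idx.append(int(sc[0]) if len(sc) else int(atoms[names == "CA"][0]))
        return np.asarray(idx)

    # -- tagging -----------------------------------------------------------
    def _tag_donors_acceptors(self):
        n = self.n_atoms
        self.is_donor = np.zeros(n, bool)
        self.donor_h = np.full(n, -1, np.int64)
        self.is_acceptor = np.zeros(n, bool)
        names = self.atom_names
        elements = np.array([guess_element(a, r) for a, r in
                             zip(names, self.resnames)])
        # acceptors: any oxygen
        self.is_acceptor[(elements == "O") & self.heavy] = True
        # peptide donors: backbone N with attached HN; charged side-chain
        # centroids (LYS/ARG) with attached HSC; water O with no explicit H
        pep = self.role == ROLE_PEPTIDE
        for i in np.flatnonzero(pep & (names == "N")):
            h = self._find_attached_h(i, "HN")
            if h >= 0:
                self.is_donor[i] = True
                self.donor_h[i] = h
        charged = pep & (names == "SC") & np.isin(self.resnames,
                                                  ["LYS", "ARG", "HIS"])
        for i in np.flatnonzero(charged):
            h = self._find_attached_h(i, "HSC")
            if h >= 0:
                self.is_donor[i] = True
                self.donor_h[i] = h

    def _find_attached_h(self, i: int, hname: str) -> int:
        same_res = np.flatnonzero(
            (self.molecule_id == self.molecule_id[i])
            & (self.resid_local == self.resid_local[i])
            & (self.atom_names == hname))
        return int(same_res[0]) if len(same_res) else -1


def assign_roles(resnames: np.ndarray) -> np.ndarray:
    role = np.zeros(len(resnames), np.int8)
    role[np.isin(resnames, list(PEPTIDE_RESNAMES))] = ROLE_PEPTIDE
    role[np.isin(resnames, list(LIPID_RESNAMES))] = ROLE_LIPID
    role[np.isin(resnames, list(WATER_RESNAMES))] = ROLE_WATER
    role[np.isin(resnames, list(ION_RESNAMES))] = ROLE_ION
    return role


def assign_lipid_groups(topology_names, resnames, role,
                        heavy, group_map=None) -> np.ndarray:
    """Map every lipid heavy atom to G1..G5; unknown names warn and get none."""
    if group_map is None:
        group_map = DMPC_GROUP_MAP
    groups = np.zeros(len(topology_names), np.int8)
    lipid_heavy = (role == ROLE_LIPID) & heavy
    unknown = set()
    for i in np.flatnonzero(lipid_heavy):
        g = group_map.get(str(topology_names[i]).upper())
        if g is None:
            unknown.add(str(topology_names[i]))
        else:
            groups[i] = g
    if unknown:
        warnings.warn(
            f"unknown lipid atom name(s) {sorted(unknown)}: excluded from "
            "G1-G5 group analyses", stacklevel=2)
    return groups


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of one independent simulation trajectory."""

    coords: np.ndarray          # (n_frames, n_atoms, 3) float32, Angstrom
    box: np.ndarray             # (n_frames, 3) Lx, Ly, Lz
    trajectory_id: int = 0
    frame_stride: int = 1       # metadata: stride used when sampling frames

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectorySet:
    """A topology shared by one or more independent trajectories.

    The trajectory (not the peptide copy) is the independent-sample unit for
    standard errors.
    """

    topology: MolecularTopology
    trajectories: list[Trajectory]

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    def total_frames(self) -> int:
        return sum(t.n_frames for t in self.trajectories)


# ---------------------------------------------------------------------------
# bilayer geometry
# ---------------------------------------------------------------------------

def frame_geometry(coords: np.ndarray, topology: MolecularTopology):
    """Per-frame bilayer geometry from leaflet phosphorus planes.

    Returns ``(z_mid, z_P_upper, z_P_lower)`` as arrays over frames (or
    scalars for a single frame).  z_P is the mass-weighted z center of the
    phosphorus atoms of each leaflet; z_mid is the midpoint of the two.
    """
    single = coords.ndim == 2
    c = coords[None] if single else coords
    p = topology.phosphorus_mask
    up = p & (topology.leaflet == LEAFLET_UPPER)
    lo = p & (topology.leaflet == LEAFLET_LOWER)
    if not up.any() or not lo.any():
        raise ValueError("empty leaflet: no phosphorus atoms assigned")
    w_up = topology.masses[up] / topology.masses[up].sum()
    w_lo = topology.masses[lo] / topology.masses[lo].sum()
    z_up = c[:, up, 2] @ w_up
    z_lo = c[:, lo, 2] @ w_lo
    z_mid = 0.5 * (z_up + z_lo)
    if single:
        return float(z_mid[0]), float(z_up[0]), float(z_lo[0])
    return z_mid, z_up, z_lo


def assign_leaflets(coords0: np.ndarray, topology: MolecularTopology,
                    later_frames: np.ndarray | None = None) -> np.ndarray:
    """Assign each lipid to a leaflet from its phosphorus z at frame 0.

    A lipid is reassigned only if it sits on the other side of the midplane
    for *every* supplied later frame (flip events are unexpected; they are
    logged).  Returns the per-atom leaflet array and stores it on the
    topology.
    """
    topo = topology
    p_idx = np.flatnonzero((topo.role == ROLE_LIPID) & (topo.atom_names == "P"))
    if len(p_idx) == 0:
        raise ValueError("no lipid phosphorus atoms in topology")
    z_mid0 = 0.5 * (coords0[p_idx, 2].max() + coords0[p_idx, 2].min())
    side0 = np.where(coords0[p_idx, 2] > z_mid0, LEAFLET_UPPER, LEAFLET_LOWER)
    side = side0.copy()
    if later_frames is not None and len(later_frames):
        z_mid = 0.5 * (later_frames[:, p_idx, 2].max(axis=1)
                       + later_frames[:, p_idx, 2].min(axis=1))
        other = later_frames[:, p_idx, 2] > z_mid[:, None]
        persistent = np.all(
            np.where(other, LEAFLET_UPPER, LEAFLET_LOWER) != side0[None], axis=0)
        if persistent.any():
            logger.warning("lipid leaflet flip detected for %d lipid(s); "
                           "reassigning", int(persistent.sum()))
            side[persistent] = -side0[persistent]
    leaflet = np.zeros(topo.n_atoms, np.int8)
    for pi, s in zip(p_idx, side):
        leaflet[topo.molecule_id == topo.molecule_id[pi]] = s
    topo.leaflet = leaflet
    return leaflet


def canonicalize_frame(coords: np.ndarray, topology: MolecularTopology,
                       peptide_copy: int):
    """Map a frame into the upper-leaflet convention of one peptide copy.

    If the analyzed peptide sits in the lower leaflet, reflect z -> 2 z_mid -
    z (distance preserving, an involution); x and y are untouched.  The
    midplane is then shifted to z = 0.  Returns ``(coords_out, leaflet_eff)``
    where ``leaflet_eff`` gives each lipid's leaflet in the canonical frame.
    """
    z_mid, _, _ = frame_geometry(coords, topology)
    out = coords.astype(np.float64, copy=True)
    leaflet_eff = topology.leaflet.copy()
    if peptide_copy == LEAFLET_LOWER:
        out[:, 2] = 2.0 * z_mid - out[:, 2]
        leaflet_eff = (-leaflet_eff).astype(np.int8)
    out[:, 2] -= z_mid
    return out, leaflet_eff


@dataclass
class PeptideView:
    """One peptide copy of one trajectory in the canonical convention.

    ``coords`` has the midplane at z = 0 and the analyzed peptide in the
    upper leaflet; ``leaflet_eff`` holds the canonical per-atom leaflet.
    """

    coords: np.ndarray
    box: np.ndarray
    topology: MolecularTopology
    copy: int
    leaflet_eff: np.ndarray
    trajectory_id: int
    z_P: np.ndarray  # canonical z_P of the peptide's leaflet, per frame

    @property
    def n_frames(self):
        return self.coords.shape[0]

    def residue_atoms(self):
        return self.topology.residue_atoms(self.copy)

    def sidechain_indices(self):
        return self.topology.sidechain_indices(self.copy)


def canonicalize_trajectory(traj: Trajectory, topology: MolecularTopology,
                            peptide_copy: int) -> PeptideView:
    """Vectorized canonicalization of all frames for one peptide copy.

    A system without a bilayer (peptide in water) is returned unchanged,
    with ``z_P`` undefined (NaN).
    """
    if not topology.phosphorus_mask.any():
        nan = np.full(traj.n_frames, np.nan)
        return PeptideView(coords=traj.coords.astype(np.float64),
                           box=traj.box, topology=topology,
                           copy=peptide_copy,
                           leaflet_eff=topology.leaflet.copy(),
                           trajectory_id=traj.trajectory_id, z_P=nan)
    z_mid, z_up, z_lo = frame_geometry(traj.coords, topology)
    out = traj.coords.astype(np.float64, copy=True)
    leaflet_eff = topology.leaflet.copy()
    if peptide_copy == LEAFLET_LOWER:
        out[:, :, 2] = 2.0 * z_mid[:, None] - out[:, :, 2]
        leaflet_eff = (-leaflet_eff).astype(np.int8)
        z_P = z_mid - z_lo  # reflected upper plane
    else:
        z_P = z_up - z_mid
    out[:, :, 2] -= z_mid[:, None]
    return PeptideView(coords=out, box=traj.box, topology=topology,
                       copy=peptide_copy, leaflet_eff=leaflet_eff,
                       trajectory_id=traj.trajectory_id, z_P=z_P)


def iter_peptide_views(trajset: TrajectorySet):
    """Lazily yield every (trajectory, peptide copy) canonical view.

    Each view holds a float64 copy of the frame coordinates, so large
    trajectory sets should be consumed one view at a time.
    """
    for traj in trajset.trajectories:
        for copy in trajset.topology.peptide_copies():
            yield canonicalize_trajectory(traj, trajset.topology, copy)


def peptide_views(trajset: TrajectorySet) -> list[PeptideView]:
    """All (trajectory, peptide copy) canonical views, pooling both copies."""
    return list(iter_peptide_views(trajset))


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def load_system(topology_file, trajectory_files, group_map=None,
                trajectory_ids=None) -> TrajectorySet:
    """Load a PDB topology plus DCD/XTC trajectories into a TrajectorySet.

    Each trajectory file becomes one independent trajectory.  Roles, lipid
    structural groups and leaflets are assigned on load.  An atom-count
    mismatch between topology and trajectory is fatal; unknown lipid atom
    names warn and are excluded from group analyses.
    """
    import MDAnalysis as mda

    if isinstance(trajectory_files, (str, Path)):
        trajectory_files = [trajectory_files]
    topology_file = str(topology_file)
    topo = None
    trajectories = []
    for k, tf in enumerate(trajectory_files):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(topology_file, str(tf))
        if topo is None:
            topo = _topology_from_universe(u, group_map)
        if len(u.atoms) != topo.n_atoms:
            raise ValueError(
                f"atom count mismatch: topology has {topo.n_atoms}, "
                f"trajectory {tf} has {len(u.atoms)}")
        coords = np.empty((len(u.trajectory), len(u.atoms), 3), np.float32)
        box = np.empty((len(u.trajectory), 3), np.float64)
        for i, ts in enumerate(u.trajectory):
            coords[i] = ts.positions
            box[i] = ts.dimensions[:3]
        tid = trajectory_ids[k] if trajectory_ids is not None else k
        trajectories.append(Trajectory(coords=coords, box=box,
                                       trajectory_id=tid))
    assign_leaflets(trajectories[0].coords[0], topo)
    _assign_peptide_copies(trajectories[0].coords[0], topo)
    return TrajectorySet(topology=topo, trajectories=trajectories)


def _topology_from_universe(u, group_map=None) -> MolecularTopology:
    names = np.array([a.name for a in u.atoms], dtype="U6")
    resnames = np.array([a.resname for a in u.atoms], dtype="U6")
    role = assign_roles(resnames)
    masses = np.array([atom_mass(n, r) for n, r in zip(names, resnames)])
    heavy = np.array([guess_element(n, r) != "H"
                      for n, r in zip(names, resnames)])
    # molecule ids: contiguous runs of (segid, resid) for peptide residues
    # belong to one molecule per segment; other roles are one molecule per
    # residue
    mol_id = np.zeros(len(names), np.int64)
    current = -1
    last_key = None
    for i, a in enumerate(u.atoms):
        if role[i] == ROLE_PEPTIDE:
            key = ("pep", a.segid, getattr(a, "chainID", ""))
        else:
            key = ("res", a.segid, getattr(a, "chainID", ""), a.resid)
        if key != last_key:
            current += 1
            last_key = key
        mol_id[i] = current
    resid_local = np.array([a.resid for a in u.atoms], np.int64)
    residue_index = np.zeros(len(names), np.int64)
    # global 1-based residue counter in file order
    counter = 0
    last = None
    for i in range(len(names)):
        key = (mol_id[i], resid_local[i])
        if key != last:
            counter += 1
            last = key
        residue_index[i] = counter
    groups = assign_lipid_groups(names, resnames, role, heavy, group_map)
    topo = MolecularTopology(
        atom_names=names, resnames=resnames, residue_index=residue_index,
        resid_local=resid_local, molecule_id=mol_id, role=role,
        lipid_group=groups, leaflet=np.zeros(len(names), np.int8),
        peptide_copy=np.zeros(len(names), np.int8), masses=masses,
        heavy=heavy)
    return topo


def _assign_peptide_copies(coords0: np.ndarray, topo: MolecularTopology):
    pep_mols = np.unique(topo.molecule_id[topo.role == ROLE_PEPTIDE])
    if len(pep_mols) == 0:
        return
    try:
        z_mid, _, _ = frame_geometry(coords0, topo)
    except ValueError:
        z_mid = 0.0  # peptide-in-water system: single copy, label upper
    for m in pep_mols:
        mask = topo.molecule_id == m
        com_z = np.average(coords0[mask, 2], weights=topo.masses[mask])
        topo.peptide_copy[mask] = (LEAFLET_UPPER if com_z >= z_mid
                                   else LEAFLET_LOWER)


def write_system(trajset: TrajectorySet, pdb_path, traj_path=None):
    """Write a TrajectorySet to PDB (topology + frame 0) and DCD/XTC."""
    import MDAnalysis as mda

    topo = trajset.topology
    n = topo.n_atoms
    n_res = int(topo.residue_index.max())
    # segment per molecule class so molecule identity survives the PDB
    # round trip: peptide copies PROA/PROB, lipids MEMB, waters SOLV, ions
    seg_of_atom = np.empty(n, dtype="U4")
    seg_of_atom[topo.role == ROLE_PEPTIDE] = "PROA"
    seg_of_atom[(topo.role == ROLE_PEPTIDE)
                & (topo.peptide_copy == LEAFLET_LOWER)] = "PROB"
    seg_of_atom[topo.role == ROLE_LIPID] = "MEMB"
    seg_of_atom[topo.role == ROLE_WATER] = "SOLV"
    seg_of_atom[topo.role == ROLE_ION] = "IONS"
    seg_labels = list(dict.fromkeys(seg_of_atom.tolist()))
    resname_per_res = [""] * n_res
    resid_per_res = [0] * n_res
    seg_per_res = np.zeros(n_res, int)
    # per-segment running resid: peptides keep their local 1..13; every
    # other molecule gets a fresh resid within its segment
    counters = {s: 0 for s in seg_labels}
    last_mol = None
    for i in range(n):
        r = topo.residue_index[i] - 1
        resname_per_res[r] = topo.resnames[i]
        seg_per_res[r] = seg_labels.index(seg_of_atom[i])
        if topo.role[i] == ROLE_PEPTIDE:
            resid_per_res[r] = int(topo.resid_local[i])
        else:
            if topo.molecule_id[i] != last_mol:
                counters[seg_of_atom[i]] += 1
            resid_per_res[r] = counters[seg_of_atom[i]]
        last_mol = topo.molecule_id[i]
    u = mda.Universe.empty(n, n_residues=n_res,
                           atom_resindex=topo.residue_index - 1,
                           residue_segindex=seg_per_res,
                           n_segments=len(seg_labels),
                           trajectory=True)
    u.add_TopologyAttr("names", topo.atom_names)
    u.add_TopologyAttr("resnames", resname_per_res)
    u.add_TopologyAttr("resids", resid_per_res)
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("masses", topo.masses)
    first = trajset.trajectories[0]
    u.atoms.positions = first.coords[0]
    u.dimensions = [*first.box[0], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
        if traj_path is not None:
            with mda.Writer(str(traj_path), n) as w:
                for traj in trajset.trajectories:
                    for i in range(traj.n_frames):
                        u.atoms.positions = traj.coords[i]
                        u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                        w.write(u.atoms)
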