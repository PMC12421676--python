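"""Intrapeptide structure probes.

Contacts (heavy-atom pairs within 4.5 A between residues separated by at
least two positions), top-contact rankings and their Spearman comparison,
Wimley-White hydrophobic moments, radius of gyration in the mean-distance
convention, end-to-end distance, geometric hydrogen bonds, and
secondary-structure aggregation from STRIDE-style assignment records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (IL_SEQUENCE, PeptideView, TrajectorySet,
                   iter_peptide_views)

CONTACT_CUTOFF = 4.5
HBOND_DISTANCE = 3.5
HBOND_ANGLE = 120.0

#: Wimley-White interfacial hydrophobicity scale: free energy of transfer
#: from water to the POPC interface, kcal/mol (positive = prefers water).
WIMLEY_WHITE_INTERFACE = {
    "ALA": 0.17, "ARG": 0.81, "ASN": 0.42, "ASP": 1.23, "CYS": -0.24,
    "GLN": 0.58, "GLU": 2.02, "GLY": 0.01, "HIS": 0.17, "ILE": -0.31,
    "LEU": -0.56, "LYS": 0.99, "MET": -0.23, "PHE": -1.13, "PRO": 0.45,
    "SER": 0.13, "THR": 0.14, "TRP": -1.85, "TYR": -0.94, "VAL": 0.07,
}

_AA3 = {"I": "ILE", "L": "LEU", "P": "PRO", "W": "TRP", "K": "LYS",
        "R": "ARG", "A": "ALA", "G": "GLY"}

#: Reference top intrapeptide contact rankings for indolicidin bound to a
#: DMPC bilayer and free in water (ensemble contact probabilities for
#: |j - i| >= 2 pairs exceeding 0.5, listed in rank order).  Used by the
#: rank-statistics utilities and as a regression reference.
IL_TOP_CONTACTS = {
    "bilayer": [
        (("TRP", 6), ("TRP", 8), 1.00), (("TRP", 9), ("TRP", 11), 1.00),
        (("LEU", 2), ("TRP", 4), 1.00), (("TRP", 11), ("ARG", 13), 0.95),
        (("TRP", 8), ("PRO", 10), 0.93), (("ILE", 1), ("PRO", 3), 0.89),
        (("TRP", 4), ("TRP", 6), 0.87), (("LYS", 5), ("PRO", 7), 0.83),
        (("PRO", 10), ("ARG", 12), 0.82), (("PRO", 7), ("TRP", 9), 0.72),
        (("PRO", 3), ("LYS", 5), 0.70),
    ],
    "water": [
        (("TRP", 9), ("TRP", 11), 1.00), (("LEU", 2), ("TRP", 4), 1.00),
        (("TRP", 6), ("TRP", 8), 1.00), (("TRP", 4), ("TRP", 6), 0.95),
        (("TRP", 11), ("ARG", 13), 0.92), (("ILE", 1), ("PRO", 3), 0.91),
        (("PRO", 3), ("LYS", 5), 0.88), (("PRO", 10), ("ARG", 12), 0.87),
        (("PRO", 7), ("TRP", 9), 0.87), (("TRP", 8), ("PRO", 10), 0.85),
        (("LYS", 5), ("PRO", 7), 0.84),
    ],
}


# ---------------------------------------------------------------------------
# contact tables
# ---------------------------------------------------------------------------

@dataclass
class ContactTable:
    """Averaged intrapeptide contact probabilities ``<C(i, j)>``.

    ``mean`` is a symmetric (n_res, n_res) matrix of contact probabilities
    for residue pairs with |j - i| >= min_sep; ``se`` holds the standard
    error over trajectories (NaN with a single trajectory).
    """

    mean: np.ndarray
    se: np.ndarray
    environment: str = "bilayer"
    min_sep: int = 2
    n_trajectories: int = 1

    def mean_contacts_per_frame(self) -> float:
        iu = np.triu_indices_from(self.mean, k=self.min_sep)
        return float(np.nansum(self.mean[iu]))

    def to_csv(self, path):
        import pandas as pd
        iu = np.triu_indices_from(self.mean, k=self.min_sep)
        pd.DataFrame({"i": iu[0] + 1, "j": iu[1] + 1,
                      "probability": self.mean[iu],
                      "se": self.se[iu]}).to_csv(path, index=False)


def contact_matrix_frames(coords, heavy_sets,
                          cutoff=CONTACT_CUTOFF, min_sep=2):
    """Per-frame boolean residue-residue contact matrices.

    ``coords``: (F, n_atoms, 3); ``heavy_sets``: list of heavy-atom index
    arrays per residue.  A pair is in contact in a frame iff any heavy-atom
    pair is closer than ``cutoff``.
    """
    n_res = len(heavy_sets)
    F = coords.shape[0]
    out = np.zeros((F, n_res, n_res), bool)
    all_idx = np.concatenate(heavy_sets)
    res_of = np.concatenate([np.full(len(h), i) for i, h in
                             enumerate(heavy_sets)])
    sub = coords[:, all_idx]
    # chunk frames to bound the (F, n, n) distance tensor
    chunk = max(1, int(4e6 / (len(all_idx) ** 2)))
    for f0 in range(0, F, chunk):
        c = sub[f0:f0 + chunk]
        d2 = np.sum((c[:, :, None, :] - c[:, None, :, :]) ** 2, axis=-1)
        hit = d2 < cutoff ** 2
        for i in range(n_res):
            mi = res_of == i
            for j in range(i + min_sep, n_res):
                h = hit[:, mi][:, :, res_of == j].any(axis=(1, 2))
                out[f0:f0 + chunk, i, j] = h
                out[f0:f0 + chunk, j, i] = h
    return out


def intrapeptide_contacts(trajset_or_views, min_sep: int = 2,
                          cutoff: float = CONTACT_CUTOFF,
                          environment: str = "bilayer") -> ContactTable:
    """Average intrapeptide contact probability matrix with per-trajectory SE.

    Both peptide copies of a trajectory pool into that trajectory's mean;
    the trajectory is the independent-sample unit.
    """
    if min_sep < 2:
        warnings.warn("contact analysis is conventionally restricted to "
                      "|j - i| >= 2", stacklevel=2)
    views = _as_views(trajset_or_views)
    per_traj = {}
    for v in views:
        groups = v.residue_atoms()
        heavy = [g[v.topology.heavy[g]] for g in groups]
        mats = contact_matrix_frames(v.coords, heavy, cutoff, min_sep)
        per_traj.setdefault(v.trajectory_id, []).append(
            mats.mean(axis=0))
    means = np.array([np.mean(m, axis=0) for m in per_traj.values()])
    mean = means.mean(axis=0)
    n = len(means)
    se = (means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.full_like(mean, np.nan))
    return ContactTable(mean=mean, se=se, environment=environment,
                        min_sep=min_sep, n_trajectories=n)


def _as_views(x):
    if isinstance(x, TrajectorySet):
        return iter_peptide_views(x)
    if isinstance(x, PeptideView):
        return [x]
    return x


# ---------------------------------------------------------------------------
# rankings and rank statistics
# ---------------------------------------------------------------------------

def rank_top_contacts(table, threshold: float = 0.5, sequence=None):
    """Ranked list of contact pairs with probability above ``threshold``.

    Accepts a :class:`ContactTable` or an ``IL_TOP_CONTACTS``-style listing.
    Returns ``[((res_i, i), (res_j, j), probability), ...]`` sorted by
    descending probability (full precision); ties break by residue indices.
    The listed order is the integer rank.
    """
    seq = sequence or IL_SEQUENCE
    if isinstance(table, ContactTable):
        entries = []
        iu = np.triu_indices_from(table.mean, k=table.min_sep)
        for i, j in zip(*iu):
            p = table.mean[i, j]
            if p > threshold:
                entries.append(((seq[i], i + 1), (seq[j], j + 1), float(p)))
        return sorted(entries, key=lambda e: (-e[2], e[0][1], e[1][1]))
    # a pre-ranked listing: the listed order is the rank among equal
    # probabilities (stable sort preserves it)
    entries = [e for e in table if e[2] > threshold]
    return sorted(entries, key=lambda e: -e[2])


def _pair_key(entry):
    return (entry[0][1], entry[1][1])


def spearman_rank_correlation(rankingA, rankingB, exclude_top_k: int = 0):
    """Spearman rho between two rankings of the same contact-pair set.

    Rankings are ordered listings (rank = list position, 1-based integer
    ranks, no mid-rank tie correction).  With ``exclude_top_k`` the top-k
    pairs of ranking A are dropped; they must coincide as a set with
    ranking B's top-k.  rho = 1 - 6 sum d^2 / (n (n^2 - 1)).
    """
    keysA = [_pair_key(e) for e in rankingA]
    keysB = [_pair_key(e) for e in rankingB]
    if set(keysA) != set(keysB):
        raise ValueError("rankings cover different contact-pair sets")
    if exclude_top_k:
        topA = set(keysA[:exclude_top_k])
        topB = set(keysB[:exclude_top_k])
        if topA != topB:
            raise ValueError("top-k sets differ between rankings")
        keysA = keysA[exclude_top_k:]
        keysB = keysB[exclude_top_k:]
    n = len(keysA)
    if n < 2:
        raise ValueError("need at least 2 pairs after exclusion")
    rankA = {k: r for r, k in enumerate(keysA, start=1)}
    rankB = {k: r for r, k in enumerate(keysB, start=1)}
    d2 = sum((rankA[k] - rankB[k]) ** 2 for k in keysA)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


def involves_residue_type(resname: str):
    """Predicate factory: does a ranked pair involve the given residue?"""
    def pred(entry):
        return entry[0][0] == resname or entry[1][0] == resname
    return pred


def group_contact_means(ranking, predicate, ndigits: int = 2):
    """Mean listed probability over pairs satisfying / not satisfying a
    predicate, rounded for reporting.  An empty group is flagged as None."""
    with_p = [e[2] for e in ranking if predicate(e)]
    without = [e[2] for e in ranking if not predicate(e)]
    mw = round(float(np.mean(with_p)), ndigits) if with_p else None
    mo = round(float(np.mean(without)), ndigits) if without else None
    return mw, mo


def delta_contacts(tableA: ContactTable, tableB: ContactTable):
    """Elementwise contact change ``<C_A> - <C_B>``.

    Returns ``(delta_matrix, mean_delta, fraction_negative)`` over pairs with
    |j - i| >= min_sep.
    """
    if tableA.mean.shape != tableB.mean.shape:
        raise ValueError("contact tables have different shapes")
    delta = tableA.mean - tableB.mean
    iu = np.triu_indices_from(delta, k=max(tableA.min_sep, tableB.min_sep))
    vals = delta[iu]
    return delta, float(vals.mean()), float(np.mean(vals < 0))


# ---------------------------------------------------------------------------
# size metrics
# ---------------------------------------------------------------------------

def radius_of_gyration(coords_heavy: np.ndarray) -> float | np.ndarray:
    """Mean distance of heavy atoms from their geometric center (A).

    This mean-distance convention differs from the conventional
    root-mean-square radius of gyration; see
    :func:`radius_of_gyration_rms` for the RMS version.
    """
    single = coords_heavy.ndim == 2
    c = coords_heavy[None] if single else coords_heavy
    center = c.mean(axis=1, keepdims=True)
    r = np.linalg.norm(c - center, axis=-1).mean(axis=1)
    return float(r[0]) if single else r


def radius_of_gyration_rms(coords_heavy: np.ndarray) -> float | np.ndarray:
    """Conventional RMS radius of gyration about the geometric center."""
    single = coords_heavy.ndim == 2
    c = coords_heavy[None] if single else coords_heavy
    center = c.mean(axis=1, keepdims=True)
    r = np.sqrt((np.linalg.norm(c - center, axis=-1) ** 2).mean(axis=1))
    return float(r[0]) if single else r


def end_to_end(view_or_coords, topology=None, copy=None):
    """Distance between the CA atoms of the first and last residue (A)."""
    if isinstance(view_or_coords, PeptideView):
        v = view_or_coords
        topo, coords, cp = v.topology, v.coords, v.copy
    else:
        coords, topo, cp = view_or_coords, topology, copy
    m = topo.peptide_mask(cp)
    ca = np.flatnonzero(m & (topo.atom_names == "CA"))
    if len(ca) == 0:
        raise ValueError("no CA atoms found for peptide")
    resids = topo.resid_local[ca]
    first = ca[np.argmin(resids)]
    last = ca[np.argmax(resids)]
    single = coords.ndim == 2
    c = coords[None] if single else coords
    d = np.linalg.norm(c[:, first] - c[:, last], axis=-1)
    return float(d[0]) if single else d


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hydrogen_bonds(coords, donors, donor_h, acceptors,
                   distance=HBOND_DISTANCE, angle=HBOND_ANGLE):
    """Geometric hydrogen bonds for one frame.

    ``donors``/``acceptors`` are atom index arrays; ``donor_h`` maps each
    donor to its hydrogen index (-1 skips the donor with a warning).  A bond
    requires d(D, A) < ``distance`` and angle D-H-A > ``angle`` degrees.
    Returns a list of (donor, hydrogen, acceptor) index triples.
    """
    donors = np.asarray(donors)
    donor_h = np.asarray(donor_h)
    acceptors = np.asarray(acceptors)
    if np.any(donor_h < 0):
        warnings.warn("donor(s) without an attached hydrogen skipped",
                      stacklevel=2)
        keep = donor_h >= 0
        donors, donor_h = donors[keep], donor_h[keep]
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    D = coords[donors]
    H = coords[donor_h]
    A = coords[acceptors]
    diff = D[:, None, :] - A[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    hd = D - H
    ha = A[None, :, :] - H[:, None, :]
    cosang = np.einsum("ij,ikj->ik", hd, ha) / (
        np.linalg.norm(hd, axis=-1)[:, None]
        * np.linalg.norm(ha, axis=-1) + 1e-30)
    cos_cut = np.cos(np.deg2rad(angle))
    ok = (dist < distance) & (cosang < cos_cut) & (dist > 1e-6)
    out = []
    for di, ai in zip(*np.nonzero(ok)):
        out.append((int(donors[di]), int(donor_h[di]), int(acceptors[ai])))
    return out


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

SS_LABELS = ("H", "G", "I", "E", "B", "T", "C")


@dataclass
class SSAssignment:
    """Per-frame per-residue secondary-structure labels plus turn records."""

    labels: np.ndarray              # (n_frames, n_res) of single characters
    beta_turns: list                # per frame: list of (i, j) residue pairs
    gamma_turns: list
    resnames: list = field(default_factory=list)

    @property
    def n_frames(self):
        return self.labels.shape[0]


@dataclass
class SSSummary:
    turn_propensity: np.ndarray     # <T(i)> per residue
    coil_propensity: np.ndarray
    mean_turn: float
    mean_coil: float
    n_beta: float
    n_gamma: float
    se_turn: float | None = None
    label_propensities: dict | None = None


def parse_stride(path) -> SSAssignment:
    """Parse STRIDE ASG records (single structure or the multi-frame
    ``REM  FRAME k`` dialect) into an :class:`SSAssignment`.

    ``LOC Turn*`` records count as beta turns, ``LOC Gamma*`` as gamma
    turns.  Malformed records are fatal, with the line number."""
    frames_labels = []
    frames_beta = []
    frames_gamma = []
    cur_labels = {}
    cur_beta, cur_gamma = [], []
    resnames = {}
    started = False

    def flush():
        nonlocal cur_labels, cur_beta, cur_gamma
        if cur_labels:
            frames_labels.append(dict(cur_labels))
            frames_beta.append(list(cur_beta))
            frames_gamma.append(list(cur_gamma))
        cur_labels, cur_beta, cur_gamma = {}, [], []

    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("REM") and "FRAME" in line:
            flush()
            started = True
            continue
        if line.startswith("ASG"):
            tok = line.split()
            try:
                resid = int(tok[3])
                code = tok[5]
            except (IndexError, ValueError) as e:
                raise ValueError(f"malformed ASG record at line {ln}") from e
            if code not in SS_LABELS:
                raise ValueError(f"unknown SS code {code!r} at line {ln}")
            cur_labels[resid] = code
            resnames[resid] = tok[1]
        elif line.startswith("LOC"):
            tok = line.split()
            try:
                kind = tok[1]
                i = int(tok[3])
                j = int(tok[6])
            except (IndexError, ValueError) as e:
                raise ValueError(f"malformed LOC record at line {ln}") from e
            if kind.startswith("Gamma"):
                cur_gamma.append((i, j))
            elif kind.startswith("Turn"):
                cur_beta.append((i, j))
    flush()
    if not frames_labels:
        raise ValueError(f"no ASG records found in {path}")
    resids = sorted(resnames)
    lab = np.empty((len(frames_labels), len(resids)), dtype="U1")
    for f, d in enumerate(frames_labels):
        for k, r in enumerate(resids):
            lab[f, k] = d.get(r, "C")
    return SSAssignment(labels=lab, beta_turns=frames_beta,
                        gamma_turns=frames_gamma,
                        resnames=[resnames[r] for r in resids])


def ss_summary(assignments, n_trajectories: int | None = None) -> SSSummary:
    """Aggregate one or more SSAssignments (one per trajectory).

    Per-residue and global turn/coil propensities, mean beta/gamma turns per
    frame, and the SE of the global turn propensity across trajectories.
    """
    if isinstance(assignments, SSAssignment):
        assignments = [assignments]
    if any(a.n_frames == 0 for a in assignments) or not assignments:
        raise ValueError("empty secondary-structure assignment")
    per_T = []
    lab_prop = {c: [] for c in SS_LABELS}
    nb, ng = [], []
    ti = []
    for a in assignments:
        ti.append((a.labels == "T").mean(axis=0))
        per_T.append(float((a.labels == "T").mean()))
        for c in SS_LABELS:
            lab_prop[c].append(float((a.labels == c).mean()))
        nb.append(np.mean([len(b) for b in a.beta_turns]))
        ng.append(np.mean([len(g) for g in a.gamma_turns]))
    turn_i = np.mean(ti, axis=0)
    coil_i = np.mean([(a.labels == "C").mean(axis=0) for a in assignments],
                     axis=0)
    n = len(assignments)
    se = (float(np.std(per_T, ddof=1) / np.sqrt(n)) if n > 1 else None)
    return SSSummary(
        turn_propensity=turn_i, coil_propensity=coil_i,
        mean_turn=float(np.mean(per_T)),
        mean_coil=float(np.mean(lab_prop["C"])),
        n_beta=float(np.mean(nb)), n_gamma=float(np.mean(ng)),
        se_turn=se,
        label_propensities={c: float(np.mean(v))
                            for c, v in lab_prop.items()})


def assign_turns_simple(view: PeptideView):
    """Approximate turn assigner for STRIDE-free operation.

    Beta turn: d(CA_i, CA_{i+3}) < 7 A; gamma turn: an i -> i+2 backbone
    hydrogen bond.  This is a simplified stand-in for a secondary-structure
    assignment program, not a reimplementation of one.
    """
    topo = view.topology
    m = topo.peptide_mask(view.copy)
    ca = np.flatnonzero(m & (topo.atom_names == "CA"))
    order = np.argsort(topo.resid_local[ca])
    ca = ca[order]
    beta = []
    gamma = []
    don = np.flatnonzero(m & topo.is_donor & (topo.atom_names == "N"))
    acc = np.flatnonzero(m & (topo.atom_names == "O"))
    for f in range(view.n_frames):
        c = view.coords[f]
        d = np.linalg.norm(c[ca[3:]] - c[ca[:-3]], axis=1)
        beta.append([(i + 1, i + 4) for i in np.flatnonzero(d < 7.0)])
        hb = hydrogen_bonds(c, don, topo.donor_h[don], acc)
        g = []
        for dn, _, ac in hb:
            ri, rj = topo.resid_local[dn], topo.resid_local[ac]
            if abs(int(ri) - int(rj)) == 2:
                g.append((int(min(ri, rj)), int(max(ri, rj))))
        gamma.append(g)
    return beta, gamma


# ---------------------------------------------------------------------------
# hydrophobic moment
# ---------------------------------------------------------------------------

def hydrophobic_moment(positions, resnames,
                       scale=WIMLEY_WHITE_INTERFACE) -> float:
    """Structure-based first-moment hydrophobicity vector magnitude.

    mu = | sum_i h_i (r_i - r_mean) | with one position per residue
    (A * kcal/mol); rotation and translation invariant.
    """
    positions = np.asarray(positions, float)
    h = []
    for r in resnames:
        key = _AA3.get(r, r).upper()
        if key not in scale:
            raise KeyError(f"residue {r!r} absent from hydrophobicity scale")
        h.append(scale[key])
    h = np.asarray(h)
    centered = positions - positions.mean(axis=0)
    return float(np.linalg.norm((h[:, None] * centered).sum(axis=0)))


def ideal_helix_positions(n_residues: int, rise: float = 1.5,
                          twist_deg: float = 100.0,
                          radius: float = 2.3) -> np.ndarray:
    """CA positions of an ideal alpha-helix (100 deg/residue, 1.5 A rise)."""
    i = np.arange(n_residues)
    a = np.deg2rad(twist_deg) * i
    return np.stack([radius * np.cos(a), radius * np.sin(a), rise * i],
                    axis=1)
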