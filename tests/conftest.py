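"""Shared fixtures: small synthetic systems reused across test modules."""

import warnings

import numpy as np
import pytest

from membind import SyntheticConfig, generate_trajectory

warnings.filterwarnings("ignore", message="unknown lipid atom")


@pytest.fixture(scope="session")
def small_system():
    """Default-condition bilayer system, 60 frames x 2 trajectories."""
    cfg = SyntheticConfig(frames=60, n_trajectories=2, seed=101)
    trajset, truth = generate_trajectory(cfg)
    return cfg, trajset, truth


@pytest.fixture(scope="session")
def clean_system():
    """Unperturbed bilayer: no planted contacts, no depression, no dimple,
    uniform chain tilt; used by geometry and bilayer-response tests."""
    cfg = SyntheticConfig(frames=80, n_trajectories=2, seed=202,
                          contact_enrichment=[], dimple_depth=0.0,
                          depression_fraction=0.0, perturb_footprint=False)
    trajset, truth = generate_trajectory(cfg)
    return cfg, trajset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def min_image_xy(d, lx, ly):
    d = np.array(d, float)
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def brute_force_residue_lipid_contacts(view, cutoff=4.5):
    """O(N^2) oracle: per-frame sets of (residue, lipid_mol, group) contacts
    from the full all-pairs heavy-atom distance matrix (no grid search),
    with the lateral minimum-image convention."""
    topo = view.topology
    pep = np.flatnonzero(topo.peptide_heavy_mask(view.copy))
    lip = np.flatnonzero(topo.lipid_heavy_mask)
    frames = []
    for f in range(view.n_frames):
        c = view.coords[f]
        lx, ly = view.box[f][:2]
        d = c[pep][:, None, :] - c[lip][None, :, :]
        d[..., 0] -= lx * np.round(d[..., 0] / lx)
        d[..., 1] -= ly * np.round(d[..., 1] / ly)
        hit = (d ** 2).sum(axis=-1) < cutoff ** 2
        rl = set()
        rlg = set()
        for a, b in zip(*np.nonzero(hit)):
            r = int(topo.resid_local[pep[a]])
            rl.add((r, int(topo.molecule_id[lip[b]])))
            rlg.add((r, int(topo.molecule_id[lip[b]]),
                     int(topo.lipid_group[lip[b]])))
        frames.append((rl, rlg))
    return frames
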