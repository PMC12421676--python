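"""Bilayer response: density fields, equal-density thickness, S_CD."""

import copy as cp
import warnings

import numpy as np
import pytest

from membind import (DensityField, SyntheticConfig, density_field,
                     expected_scd, generate_trajectory, region_density,
                     s_cd, thickness_profile)
from membind.core import (MolecularTopology, PeptideView, ROLE_LIPID,
                          ROLE_PEPTIDE, iter_peptide_views)
from membind.synth import build_topology


def _point_cloud_view(rng, n_atoms=3000, n_frames=40, box=(40.0, 40.0, 60.0),
                      z_range=(-20.0, 20.0)):
    """A fake system: one peptide atom pinned at the origin plus uniformly
    distributed lipid point atoms, for Poisson-counting density checks."""
    names = np.array(["CA"] + ["C1"] * n_atoms, dtype="U6")
    resnames = np.array(["TRP"] + ["DMPC"] * n_atoms, dtype="U6")
    role = np.array([ROLE_PEPTIDE] + [ROLE_LIPID] * n_atoms, np.int8)
    n = n_atoms + 1
    topo = MolecularTopology(
        atom_names=names, resnames=resnames,
        residue_index=np.arange(1, n + 1),
        resid_local=np.ones(n, np.int64),
        molecule_id=np.arange(n), role=role,
        lipid_group=np.zeros(n, np.int8),
        leaflet=np.zeros(n, np.int8),
        peptide_copy=np.array([1] + [0] * n_atoms, np.int8),
        masses=np.full(n, 12.0), heavy=np.ones(n, bool))
    coords = np.empty((n_frames, n, 3))
    coords[:, 0] = 0.0
    coords[:, 1:, 0] = rng.uniform(-box[0] / 2, box[0] / 2,
                                   (n_frames, n_atoms))
    coords[:, 1:, 1] = rng.uniform(-box[1] / 2, box[1] / 2,
                                   (n_frames, n_atoms))
    coords[:, 1:, 2] = rng.uniform(*z_range, (n_frames, n_atoms))
    return PeptideView(coords=coords, box=np.tile(np.array(box),
                                                  (n_frames, 1)),
                       topology=topo, copy=1,
                       leaflet_eff=topo.leaflet, trajectory_id=0,
                       z_P=np.full(n_frames, 17.4))


class TestDensityField:
    def test_uniform_cloud_recovers_number_density(self, rng):
        """Uniformly placed atoms at known density give every bin that
        density within ~3 Poisson SE."""
        v = _point_cloud_view(rng)
        rho = 3000 / (40.0 * 40.0 * 40.0)
        fld = density_field([v], dr=4.0, dz=8.0, z_max=16.0)
        lam = fld.bin_volumes * fld.n_frames * rho   # expected counts
        counts = fld.lipid * fld.bin_volumes * fld.n_frames
        zscore = (counts - lam) / np.sqrt(lam)
        assert np.abs(zscore).max() < 4.0
        assert np.abs(fld.lipid / rho - 1).mean() < 0.05

    def test_atom_count_conserved(self, rng):
        """Sum of density x bin volume x frames equals the number of atoms
        inside the cylindrical grid, exactly."""
        v = _point_cloud_view(rng, n_frames=5)
        fld = density_field([v], dr=1.0, dz=1.0, z_max=20.0)
        total = (fld.lipid * fld.bin_volumes).sum() * fld.n_frames
        inside = 0
        r_max = fld.r_edges[-1]
        for f in range(5):
            c = v.coords[f, 1:]
            r = np.hypot(c[:, 0], c[:, 1])
            inside += int(((r < r_max) & (np.abs(c[:, 2]) < 20.0)).sum())
        assert total == pytest.approx(inside, abs=1.5)

    def test_r_max_truncated_with_warning(self, rng):
        v = _point_cloud_view(rng, n_frames=2)
        with pytest.warns(UserWarning, match="truncated"):
            fld = density_field([v], r_max=100.0)
        assert fld.r_edges[-1] <= 20.0 + 1.0

    def test_empty_bins_zero(self, rng):
        v = _point_cloud_view(rng, n_frames=2, z_range=(-5.0, 5.0))
        fld = density_field([v], dz=2.0)
        zc = fld.z_centers
        assert (fld.lipid[:, np.abs(zc) > 8] == 0).all()


class TestRegionDensity:
    def test_uniform_field_near_equals_away(self):
        r_edges = np.arange(0, 21.0, 1.0)
        z_edges = np.arange(-20, 21.0, 1.0)
        shape = (len(r_edges) - 1, len(z_edges) - 1)
        fld = DensityField(lipid=np.full(shape, 0.03),
                           water=np.zeros(shape), r_edges=r_edges,
                           z_edges=z_edges, n_frames=1)
        near, away = region_density(fld)
        assert near == pytest.approx(away, abs=1e-12)

    def test_planted_depression_recovered(self, rng):
        """A 21% lateral density depression inside r_c is recovered from
        the head-group slab as a near/away ratio drop of 0.21 +/- 0.04,
        using an unperturbed run as the baseline."""
        ratios = {}
        for f in (0.21, 0.0):
            cfg = SyntheticConfig(frames=150, n_trajectories=2, seed=909,
                                  contact_enrichment=[], dimple_depth=0.0,
                                  perturb_footprint=False,
                                  depression_fraction=f)
            ts, _ = generate_trajectory(cfg)
            fld = density_field(ts)
            near, away = region_density(fld, z_slab=(10.0, 20.0))
            ratios[f] = near / away
        assert ratios[0.21] / ratios[0.0] == pytest.approx(1 - 0.21,
                                                           abs=0.04)


class TestThickness:
    @staticmethod
    def _ramp_field(surface_of_r, z_max=30.0, dr=1.0, dz=1.0, r_max=20.0):
        """Fields whose lipid-water density difference is an exact linear
        ramp crossing zero at +/- surface(r)."""
        r_edges = np.arange(0, r_max + dr, dr)
        z_edges = np.arange(-z_max, z_max + dz, dz)
        rc = 0.5 * (r_edges[:-1] + r_edges[1:])
        zc = 0.5 * (z_edges[:-1] + z_edges[1:])
        lip = np.zeros((len(rc), len(zc)))
        wat = np.zeros_like(lip)
        for i, r in enumerate(rc):
            s = surface_of_r(r)
            diff = (s - np.abs(zc)) * 1e-3
            lip[i] = np.where(diff > 0, diff, 0.0)
            wat[i] = np.where(diff < 0, -diff, 0.0)
        return DensityField(lipid=lip, water=wat, r_edges=r_edges,
                            z_edges=z_edges, n_frames=1)

    def test_flat_slab_thickness_exact(self):
        """A lipid slab with surfaces at |z| = 18 yields D(r) = 36
        everywhere."""
        fld = self._ramp_field(lambda r: 18.0)
        th = thickness_profile(fld)
        assert np.allclose(th.D, 36.0, atol=1e-9)
        assert th.delta_D_near == pytest.approx(0.0, abs=1e-9)

    def test_swapping_fields_keeps_crossings(self):
        fld = self._ramp_field(lambda r: 18.0)
        swapped = DensityField(lipid=fld.water, water=fld.lipid,
                               r_edges=fld.r_edges, z_edges=fld.z_edges,
                               n_frames=1)
        assert np.allclose(thickness_profile(swapped).D,
                           thickness_profile(fld).D, atol=1e-9)

    def test_planted_dimple_recovered(self):
        """A flat-bottomed 12 A indentation of the upper surface inside r_c
        appears as delta_D_center = 12 up to interpolation error."""
        def surf(r):
            if r < 6.0:
                return 6.0
            if r < 13.0:
                return 6.0 + 12.0 * (r - 6.0) / 7.0
            return 18.0

        # dimple the upper surface only: build asymmetric ramp manually
        base = self._ramp_field(lambda r: 18.0)
        dim = self._ramp_field(surf)
        lip = base.lipid.copy()
        wat = base.water.copy()
        upper = base.z_centers > 0
        lip[:, upper] = dim.lipid[:, upper]
        wat[:, upper] = dim.water[:, upper]
        fld = DensityField(lipid=lip, water=wat, r_edges=base.r_edges,
                           z_edges=base.z_edges, n_frames=1)
        th = thickness_profile(fld)
        assert th.delta_D_center == pytest.approx(12.0, abs=0.05)

    def test_no_crossing_masked_with_warning(self):
        fld = self._ramp_field(lambda r: 18.0)
        fld.water[:5] = 0.0    # lipid-only bins at small r: no crossing
        with pytest.warns(UserWarning, match="without an equal-density"):
            th = thickness_profile(fld)
        assert np.isnan(th.D[:5]).all()
        assert np.isfinite(th.D[6:]).all()

    def test_unperturbed_bilayer_flat(self, clean_system):
        """D(r) on the unperturbed synthetic bilayer varies by less than
        two z-bins."""
        _, ts, _ = clean_system
        fld = density_field(ts)
        th = thickness_profile(fld)
        ok = np.isfinite(th.D)
        assert np.abs(th.D[ok] - np.nanmean(th.D)).max() < 2.0


class TestOrderParameter:
    def test_isotropic_ch_orientations_give_zero(self, rng):
        """Randomly oriented C-H bonds give S_CD -> 0 within 3 SE."""
        cfg = SyntheticConfig(frames=1, n_trajectories=1, seed=0,
                              lipids_per_leaflet=1, box=(20.0, 20.0, 60.0),
                              water_slab_density=0.0,
                              contact_enrichment=[])
        topo, meta = build_topology(cfg)
        F = 1500
        n = topo.n_atoms
        coords = np.zeros((F, n, 3))
        ci_names = [f"C2{i}" for i in range(2, 15)]
        # isotropic H directions around each carbon
        for m in np.unique(topo.molecule_id[topo.role == ROLE_LIPID]):
            atoms = np.flatnonzero(topo.molecule_id == m)
            names = {topo.atom_names[a]: a for a in atoms}
            for pos in range(2, 15):
                c_idx = names[f"C2{pos}"]
                coords[:, c_idx] = rng.normal(0, 5, (F, 3))
                for hn in (f"H{pos}R", f"H{pos}S"):
                    u = rng.normal(0, 1, (F, 3))
                    u /= np.linalg.norm(u, axis=1, keepdims=True)
                    coords[:, names[hn]] = coords[:, c_idx] + 1.09 * u
        view = PeptideView(coords=coords,
                           box=np.tile([20.0, 20.0, 60.0], (F, 1)),
                           topology=topo, copy=1, leaflet_eff=topo.leaflet,
                           trajectory_id=0, z_P=np.full(F, 17.4))
        op = s_cd([view])
        n_samples = F * 2 * 13 * 2
        se = np.sqrt(0.2 / n_samples)   # var[(3cos^2-1)/2] = 1/5
        assert abs(op.mean_minus_scd()) < 3.5 * se
        assert (op.minus_scd >= -1.0).all() and (op.minus_scd <= 0.5).all()

    def test_planted_tilt_matches_closed_form(self, clean_system):
        """Uniform chain-tilt concentration: measured -<S_CD> matches the
        analytic expectation of the tilt model."""
        cfg, ts, truth = clean_system
        op = s_cd(ts)
        assert op.mean_minus_scd() == pytest.approx(
            -truth.expected_scd_bulk, abs=0.004)

    def test_contact_split_direction(self, small_system):
        """Footprint lipids carry the lower tilt concentration, so in-contact
        chains are less ordered than bulk chains."""
        _, ts, truth = small_system
        op = s_cd(ts, contact_split=True)
        assert op.mean_minus_scd(contact=True) < op.mean_minus_scd(False)

    def test_missing_hydrogens_fatal(self, small_system):
        _, ts, _ = small_system
        topo = ts.topology
        names = topo.atom_names.copy()
        topo.atom_names = np.where(names == "H2R", "XXR", names)
        try:
            with pytest.raises(ValueError, match="missing sn-2 hydrogen"):
                s_cd(ts)
        finally:
            topo.atom_names = names
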