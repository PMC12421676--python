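"""Intrapeptide structure probes: contacts, rank statistics, size metrics,
hydrogen bonds, secondary-structure parsing, hydrophobic moments."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from membind import (IL_TOP_CONTACTS, WIMLEY_WHITE_INTERFACE, ContactTable,
                     delta_contacts, end_to_end, group_contact_means,
                     hydrogen_bonds, hydrophobic_moment,
                     intrapeptide_contacts, involves_residue_type,
                     parse_stride, radius_of_gyration,
                     radius_of_gyration_rms, rank_top_contacts,
                     spearman_rank_correlation, ss_summary)
from membind.core import iter_peptide_views
from membind.peptide import contact_matrix_frames, ideal_helix_positions


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestIntrapeptideContacts:
    @pytest.mark.parametrize("gap,expected", [(4.4, True), (4.6, False)])
    def test_heavy_atom_threshold(self, gap, expected):
        """Closest heavy-atom pair at 4.4 A is a contact; 4.6 A is not."""
        # 3 single-atom 'residues' on a line; pair (0, 2) separated by gap
        coords = np.array([[[0, 0, 0], [50, 0, 0], [gap, 0, 0]]], float)
        heavy = [np.array([0]), np.array([1]), np.array([2])]
        mats = contact_matrix_frames(coords, heavy)
        assert bool(mats[0, 0, 2]) is expected

    def test_matches_brute_force_oracle(self, small_system):
        """Module contact table equals an exhaustive O(n^2) pairwise scan
        on a 20-frame fixture (exact)."""
        _, ts, _ = small_system
        v = next(iter_peptide_views(ts))
        topo = v.topology
        groups = v.residue_atoms()
        heavy = [g[topo.heavy[g]] for g in groups]
        F = 20
        mats = contact_matrix_frames(v.coords[:F], heavy)
        for f in range(F):
            c = v.coords[f]
            for i in range(13):
                for j in range(i + 2, 13):
                    dmin = min(np.linalg.norm(c[a] - c[b])
                               for a in heavy[i] for b in heavy[j])
                    assert mats[f, i, j] == (dmin < 4.5)

    def test_min_sep_warning(self, small_system):
        _, ts, _ = small_system
        v = next(iter_peptide_views(ts))
        with pytest.warns(UserWarning, match="restricted"):
            intrapeptide_contacts([v], min_sep=1)

    def test_table_symmetric_and_bounded(self, small_system):
        _, ts, _ = small_system
        table = intrapeptide_contacts(ts)
        assert np.allclose(table.mean, table.mean.T)
        assert (table.mean >= 0).all() and (table.mean <= 1).all()
        assert table.n_trajectories == 2


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

class TestRankings:
    def test_reference_listing_rank_order(self):
        ranked = rank_top_contacts(IL_TOP_CONTACTS["bilayer"])
        assert len(ranked) == 11
        assert ranked[0][0] == ("TRP", 6) and ranked[0][1] == ("TRP", 8)
        assert ranked[0][2] == 1.00

    def test_empty_and_tie_rule(self):
        assert rank_top_contacts([]) == []
        # in a computed table, ties break by residue index
        m = np.zeros((13, 13))
        m[8, 10] = m[10, 8] = 0.9
        m[0, 2] = m[2, 0] = 0.9
        table = ContactTable(mean=m, se=np.zeros_like(m))
        ranked = rank_top_contacts(table)
        assert ranked[0][0] == ("ILE", 1)
        # in a pre-ranked listing the printed order is preserved
        tied = [(("TRP", 9), ("TRP", 11), 0.9), (("ILE", 1), ("PRO", 3), 0.9)]
        assert rank_top_contacts(tied)[0][0] == ("TRP", 9)

    def test_threshold_filters(self):
        entries = [(("TRP", 6), ("TRP", 8), 0.6), (("ILE", 1), ("PRO", 3),
                                                   0.4)]
        assert len(rank_top_contacts(entries, threshold=0.5)) == 1

    def test_from_contact_table(self):
        m = np.zeros((13, 13))
        m[0, 2] = m[2, 0] = 0.9
        m[3, 5] = m[5, 3] = 0.7
        table = ContactTable(mean=m, se=np.zeros_like(m))
        ranked = rank_top_contacts(table)
        assert [(e[0][1], e[1][1]) for e in ranked] == [(1, 3), (4, 6)]


class TestSpearman:
    def test_identical_is_one(self):
        r = IL_TOP_CONTACTS["bilayer"]
        assert spearman_rank_correlation(r, r) == pytest.approx(1.0)

    def test_mismatched_sets_fatal(self):
        a = IL_TOP_CONTACTS["bilayer"]
        with pytest.raises(ValueError, match="different contact-pair"):
            spearman_rank_correlation(a, a[:-1])

    def test_too_few_after_exclusion_fatal(self):
        a = IL_TOP_CONTACTS["bilayer"][:4]
        b = [a[2], a[1], a[0], a[3]]
        with pytest.raises(ValueError, match="at least 2"):
            spearman_rank_correlation(a, b, exclude_top_k=3)

    def test_matches_scipy_on_random_permutations(self, rng):
        """Integer-rank Spearman equals the reference statistics
        implementation to 1e-12 on permutation-generated rankings."""
        base = IL_TOP_CONTACTS["bilayer"]
        for _ in range(25):
            perm = rng.permutation(len(base))
            other = [base[i] for i in perm]
            rho = spearman_rank_correlation(base, other)
            ranks_a = np.arange(1, len(base) + 1)
            ranks_b = np.empty(len(base))
            ranks_b[perm] = np.arange(1, len(base) + 1)
            ref = spearmanr(ranks_a, ranks_b).statistic
            assert rho == pytest.approx(ref, abs=1e-12)


class TestGroupMeans:
    def test_single_pair_table_flags_empty_group(self):
        single = [(("TRP", 6), ("TRP", 8), 0.9)]
        mw, mo = group_contact_means(single, involves_residue_type("TRP"))
        assert mw == 0.9 and mo is None


class TestDeltaContacts:
    def test_trivial_and_random_oracle(self, rng):
        m = rng.random((13, 13))
        m = (m + m.T) / 2
        t1 = ContactTable(mean=m, se=np.zeros_like(m))
        t0 = ContactTable(mean=np.zeros_like(m), se=np.zeros_like(m))
        d, mean_d, frac_neg = delta_contacts(t1, t1)
        assert np.allclose(d, 0) and mean_d == 0 and frac_neg == 0
        ones = ContactTable(mean=np.ones_like(m), se=np.zeros_like(m))
        d, _, _ = delta_contacts(ones, t0)
        assert np.allclose(d, 1)
        d, mean_d, frac_neg = delta_contacts(t0, t1)
        iu = np.triu_indices(13, k=2)
        assert np.allclose(d, -m)
        assert mean_d == pytest.approx(-m[iu].mean())
        assert frac_neg == pytest.approx(np.mean(m[iu] > 0))

    def test_shape_mismatch_fatal(self):
        a = ContactTable(mean=np.zeros((13, 13)), se=np.zeros((13, 13)))
        b = ContactTable(mean=np.zeros((12, 12)), se=np.zeros((12, 12)))
        with pytest.raises(ValueError):
            delta_contacts(a, b)


# ---------------------------------------------------------------------------
# size metrics
# ---------------------------------------------------------------------------

class TestSizeMetrics:
    def test_rg_mean_distance_convention(self, rng):
        """Single atom 0; two atoms 2 A apart give 1.0 (mean distance from
        the geometric center); random frame matches the direct sum."""
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0, 0, 0], [2, 0, 0]], float)
        assert radius_of_gyration(two) == pytest.approx(1.0)
        c = rng.normal(0, 4, (50, 3))
        ref = np.mean(np.linalg.norm(c - c.mean(axis=0), axis=1))
        assert radius_of_gyration(c) == pytest.approx(ref, abs=1e-12)

    def test_mean_distance_below_rms(self, rng):
        """Jensen: the mean-distance radius never exceeds the RMS radius."""
        for _ in range(10):
            c = rng.normal(0, 3, (30, 3))
            assert radius_of_gyration(c) <= radius_of_gyration_rms(c) + 1e-12

    def test_end_to_end(self, small_system):
        _, ts, _ = small_system
        v = next(iter_peptide_views(ts))
        topo = v.topology
        ca = np.flatnonzero(topo.peptide_mask(v.copy)
                            & (topo.atom_names == "CA"))
        ref = np.linalg.norm(v.coords[0, ca[0]] - v.coords[0, ca[-1]])
        assert end_to_end(v)[0] == pytest.approx(ref, abs=1e-9)

    def test_end_to_end_missing_ca_fatal(self, small_system):
        _, ts, _ = small_system
        v = next(iter_peptide_views(ts))
        topo = v.topology
        names = topo.atom_names.copy()
        topo.atom_names = np.where(names == "CA", "CX", names)
        try:
            with pytest.raises(ValueError, match="CA"):
                end_to_end(v)
        finally:
            topo.atom_names = names


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

class TestHydrogenBonds:
    def _frame(self, d, angle_deg):
        """Donor at origin, H 1 A along +x; acceptor at distance d from D
        making the requested D-H-A angle."""
        D = np.array([0.0, 0.0, 0.0])
        H = np.array([1.0, 0.0, 0.0])
        # place A such that angle D-H-A = angle_deg and |DA| = d
        # solve on the xy plane
        best = None
        for t in np.linspace(0, np.pi, 20001):
            A = np.array([d * np.cos(t), d * np.sin(t), 0.0])
            v1 = D - H
            v2 = A - H
            ang = np.degrees(np.arccos(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
            if best is None or abs(ang - angle_deg) < best[0]:
                best = (abs(ang - angle_deg), A)
        return np.stack([D, H, best[1]])

    @pytest.mark.parametrize("d,angle,expected", [
        (3.4, 170.0, True),   # within both thresholds
        (3.4, 100.0, False),  # angle fails
        (3.6, 180.0, False),  # distance fails
    ])
    def test_geometric_criteria(self, d, angle, expected):
        c = self._frame(d, angle)
        bonds = hydrogen_bonds(c, donors=[0], donor_h=[1], acceptors=[2])
        assert (len(bonds) == 1) is expected

    def test_donor_without_hydrogen_skipped(self):
        c = self._frame(3.0, 170.0)
        with pytest.warns(UserWarning, match="without an attached"):
            bonds = hydrogen_bonds(c, donors=[0], donor_h=[-1],
                                   acceptors=[2])
        assert bonds == []


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

class TestStrideParsing:
    def test_all_coil_gives_zero_turn(self, tmp_path):
        lines = ["REM  FRAME 1"]
        for i in range(1, 14):
            lines.append(f"ASG  TRP A {i:4d} {i:4d}    C   Coil"
                         "   360.00 360.00 0.0")
        p = tmp_path / "ss.txt"
        p.write_text("\n".join(lines))
        summ = ss_summary(parse_stride(p))
        assert summ.mean_turn == 0.0
        assert summ.mean_coil == 1.0
        assert summ.n_beta == 0.0

    def test_malformed_record_fatal_with_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("REM  FRAME 1\nASG  TRP A broken\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_stride(p)

    def test_empty_assignment_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("REM  FRAME 1\n")
        with pytest.raises(ValueError):
            parse_stride(p)

    def test_label_propensities_normalize(self, tmp_path):
        from membind import SyntheticConfig, emit_stride_like_assignments
        cfg = SyntheticConfig(frames=200, n_trajectories=1, seed=77)
        emit_stride_like_assignments(cfg, tmp_path / "ss.txt")
        summ = ss_summary(parse_stride(tmp_path / "ss.txt"))
        assert sum(summ.label_propensities.values()) == pytest.approx(1.0)
        assert np.allclose(summ.turn_propensity + summ.coil_propensity, 1.0)


# ---------------------------------------------------------------------------
# hydrophobic moment
# ---------------------------------------------------------------------------

class TestHydrophobicMoment:
    def test_zero_scale_gives_zero(self):
        pos = ideal_helix_positions(13)
        scale = {r: 0.0 for r in WIMLEY_WHITE_INTERFACE}
        assert hydrophobic_moment(pos, ["TRP"] * 13, scale) == 0.0

    def test_rotation_invariance(self, rng):
        pos = ideal_helix_positions(13)
        res = ["ILE", "LEU", "PRO", "TRP", "LYS", "TRP", "PRO", "TRP",
               "TRP", "PRO", "TRP", "ARG", "ARG"]
        mu = hydrophobic_moment(pos, res)
        th = np.pi / 2
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        assert hydrophobic_moment(pos @ R.T + 7.5, res) == pytest.approx(
            mu, abs=1e-9)

    def test_three_residue_hand_computed(self):
        """mu for three residues at printed positions equals the vector sum
        evaluated by hand: r = (0,0,0),(1,0,0),(2,0,0), h = (1, -2, 1)
        => sum h_i (r_i - r_mean) = 1*(-1,0,0) + -2*(0,0,0) + 1*(1,0,0)
        = (0,0,0)... with h = (1, -2, 3): (-1+3, 0, 0) = (2,0,0), mu = 2."""
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        scale = {"ALA": 1.0, "GLY": -2.0, "SER": 3.0}
        mu = hydrophobic_moment(pos, ["ALA", "GLY", "SER"], scale)
        assert mu == pytest.approx(2.0, abs=1e-12)

    def test_unknown_residue_fatal(self):
        with pytest.raises(KeyError):
            hydrophobic_moment(np.zeros((1, 3)), ["XXX"])
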