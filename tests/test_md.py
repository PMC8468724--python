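"""MD statistics tests: drift, RMSF, distances, H-bonds, occupancy, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from dualscreen.md import (
    ATOM_COLUMNS,
    HBond,
    HBondMatrix,
    DistanceSeries,
    Trajectory,
    binned_hbond_counts,
    detect_hbonds,
    distance_distribution,
    energy_drift,
    fraction_within,
    min_distance_series,
    occupancy_stats,
    rmsf,
    superpose_frames,
)
from dualscreen.synthetic import SyntheticSpec, gen_energy_series, gen_trajectory


def atom_row(atom_id, residue_id=1, name="ALA", chain="A", element="C",
             donor=False, acceptor=False, ligand=False, parent=-1):
    return dict(atom_id=atom_id, residue_id=residue_id, residue_name=name,
                chain=chain, element=element, is_donor=donor,
                is_acceptor=acceptor, is_ligand=ligand, parent_donor=parent)


def make_traj(coords, rows, times=None):
    coords = np.asarray(coords, dtype=float)
    times = np.arange(coords.shape[0]) * 10.0 if times is None else times
    return Trajectory(times, coords, pd.DataFrame(rows, columns=ATOM_COLUMNS))


class TestEnergyDrift:
    def test_constant_series_passes(self):
        t = np.arange(100.0)
        result = energy_drift(t, np.full(100, -5.0e5))
        assert result.slope_per_ns == 0.0 and result.passed

    def test_planted_drift_recovered(self):
        t, e, planted = gen_energy_series(SyntheticSpec(seed=1, drift_rate=0.05))
        result = energy_drift(t, e)
        assert result.relative_drift == pytest.approx(planted, abs=0.005)
        assert not result.passed

    def test_white_noise_below_tolerance(self):
        t, e, _ = gen_energy_series(SyntheticSpec(seed=2, drift_rate=0.0))
        assert energy_drift(t, e).passed

    def test_constant_time_errors(self):
        with pytest.raises(ValueError):
            energy_drift(np.zeros(20), np.arange(20.0))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            energy_drift(np.arange(5.0), np.arange(5.0))


def brute_force_rmsf(coords):
    """Independent two-pass per-atom RMSF (no superposition)."""
    out = []
    for a in range(coords.shape[1]):
        mean = coords[:, a, :].mean(axis=0)
        sq = 0.0
        for f in range(coords.shape[0]):
            sq += ((coords[f, a] - mean) ** 2).sum()
        out.append(np.sqrt(sq / coords.shape[0]))
    return np.array(out)


class TestRMSF:
    def test_frozen_residue_zero(self):
        traj, _ = gen_trajectory(SyntheticSpec(seed=1, sigma_fluct=0.0),
                                 n_frames=50, n_residues=3, with_ligand=False)
        assert rmsf(traj)["rmsf"].to_numpy() == pytest.approx(np.zeros(3), abs=1e-12)

    def test_two_point_alternation(self):
        # one residue alternating +-1 A about the mean along x, others frozen
        coords = np.zeros((10, 2, 3))
        coords[::2, 0, 0] = 1.0
        coords[1::2, 0, 0] = -1.0
        coords[:, 1, 0] = 50.0
        traj = make_traj(coords, [atom_row(0, 1), atom_row(1, 2)])
        prof = rmsf(traj, superpose=False)
        assert prof["rmsf"].to_numpy() == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_isotropic_jitter_recovers_chi_mean(self):
        traj, truth = gen_trajectory(SyntheticSpec(seed=3, sigma_fluct=0.5),
                                     n_frames=10_000, n_residues=4, with_ligand=False)
        got = rmsf(traj, superpose=False)["rmsf"].to_numpy()
        assert got == pytest.approx(0.5 * np.sqrt(3), rel=0.02)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(30, 5, 3))
        traj = make_traj(coords, [atom_row(i, i + 1) for i in range(5)])
        got = rmsf(traj, superpose=False)["rmsf"].to_numpy()
        assert got == pytest.approx(brute_force_rmsf(coords), rel=1e-10)

    def test_superposition_never_increases_total_msd(self):
        rng = np.random.default_rng(4)
        base = rng.normal(scale=3.0, size=(6, 3))
        coords = np.empty((40, 6, 3))
        for f in range(40):  # rigid rotation + drift + small jitter
            rot = Rotation.from_rotvec(rng.normal(scale=0.2, size=3))
            coords[f] = rot.apply(base) + rng.normal(scale=0.05, size=(6, 3)) + f * 0.1
        traj = make_traj(coords, [atom_row(i, i + 1) for i in range(6)])
        fitted = superpose_frames(traj)

        def total_msd(c):
            return ((c - c.mean(axis=0, keepdims=True)) ** 2).sum()

        assert total_msd(fitted.coords) <= total_msd(traj.coords) + 1e-9

    def test_missing_residue_errors(self):
        traj, _ = gen_trajectory(SyntheticSpec(seed=1), n_frames=5, n_residues=2)
        with pytest.raises(KeyError):
            rmsf(traj, residue_ids=[99])


class TestMinDistance:
    def test_single_atoms(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0
        traj = make_traj(coords, [atom_row(0, 1), atom_row(1, 2, ligand=True)])
        series = min_distance_series(traj, reference_residue=1)
        assert series.d_min[0] == pytest.approx(3.0)

    def test_minimum_over_ligand_atoms(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 0] = 3.0
        coords[0, 2, 0] = 7.0
        traj = make_traj(coords, [atom_row(0, 1),
                                  atom_row(1, 2, ligand=True),
                                  atom_row(2, 2, ligand=True)])
        assert min_distance_series(traj, reference_residue=1).d_min[0] == pytest.approx(3.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(scale=5.0, size=(8, 20, 3))
        rows = [atom_row(i, 1) for i in range(10)] + \
               [atom_row(10 + i, 2, ligand=True) for i in range(10)]
        traj = make_traj(coords, rows)
        series = min_distance_series(traj, reference_residue=1)
        for f in range(8):
            best = min(
                np.linalg.norm(coords[f, i] - coords[f, 10 + j])
                for i in range(10) for j in range(10)
            )
            assert series.d_min[f] == pytest.approx(best, rel=1e-12)

    def test_empty_selection_errors(self):
        traj, _ = gen_trajectory(SyntheticSpec(seed=1), n_frames=3, n_residues=2,
                                 with_ligand=False)
        with pytest.raises(ValueError):
            min_distance_series(traj, reference_residue=1)


class TestFractionWithin:
    @pytest.mark.parametrize("d,expected", [(3.0, 1.0), (9.0, 0.0)])
    def test_trivial(self, d, expected):
        series = DistanceSeries(np.arange(5.0), np.full(5, d))
        assert fraction_within(series) == expected

    def test_planted_fraction_exact(self):
        traj, truth = gen_trajectory(SyntheticSpec(seed=5, frac_within=0.164),
                                     n_frames=1000, n_residues=3)
        series = min_distance_series(traj, reference_residue=1)
        assert fraction_within(series) == truth.frac_within == 0.164

    def test_cutoff_is_strict(self):
        series = DistanceSeries(np.arange(2.0), np.array([5.0, 4.9]))
        assert fraction_within(series, cutoff=5.0) == 0.5


class TestDistanceDistribution:
    def test_density_integrates_to_one(self):
        series = DistanceSeries(np.arange(500.0),
                                np.random.default_rng(0).normal(5, 1, 500))
        grid, dens = distance_distribution(series)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_shows_two_modes(self):
        rng = np.random.default_rng(1)
        d = np.r_[rng.normal(3, 0.2, 300), rng.normal(8, 0.2, 300)]
        grid, dens = distance_distribution(DistanceSeries(np.arange(600.0), d))
        peaks = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]) & (dens[1:-1] > dens.max() / 10)
        assert peaks.sum() == 2

    def test_degenerate_series_concentrates_mass(self):
        series = DistanceSeries(np.arange(20.0), np.full(20, 4.2))
        grid, dens = distance_distribution(series)
        assert grid[np.argmax(dens)] == pytest.approx(4.2, abs=1e-3)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


def hbond_system(d_pos, h_pos, a_pos, n_frames=1):
    """Ligand donor (with hydrogen) + protein acceptor toy system."""
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 0] = d_pos
    coords[:, 1] = h_pos
    coords[:, 2] = a_pos
    rows = [
        atom_row(0, 99, name="LIG", chain="X", element="N", donor=True, ligand=True),
        atom_row(1, 99, name="LIG", chain="X", element="H", ligand=True, parent=0),
        atom_row(2, 7, name="SER", element="O", acceptor=True),
    ]
    return make_traj(coords, rows)


class TestDetectHbonds:
    def test_inside_both_cutoffs(self):
        # D-A 3.0 A, H on the D->A axis (angle 0)
        traj = hbond_system([0, 0, 0], [1, 0, 0], [3, 0, 0])
        matrix = detect_hbonds(traj)
        assert len(matrix.bonds) == 1 and matrix.existence[0, 0] == 1
        assert matrix.bonds[0].partner_residue == "A:SER:7"

    def test_distance_failure(self):
        traj = hbond_system([0, 0, 0], [1, 0, 0], [3.6, 0, 0])
        assert len(detect_hbonds(traj).bonds) == 0

    def test_angle_failure(self):
        # H perpendicular to D->A: angle 90 degrees
        traj = hbond_system([0, 0, 0], [0, 1, 0], [3, 0, 0])
        assert len(detect_hbonds(traj).bonds) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        n_frames = 200
        coords = np.zeros((n_frames, 3, 3))
        coords[:, 0] = rng.normal(scale=1.5, size=(n_frames, 3))
        coords[:, 1] = coords[:, 0] + rng.normal(scale=0.7, size=(n_frames, 3))
        coords[:, 2] = rng.normal(scale=2.0, size=(n_frames, 3))
        rows = [
            atom_row(0, 99, chain="X", donor=True, ligand=True),
            atom_row(1, 99, chain="X", ligand=True, parent=0),
            atom_row(2, 7, acceptor=True),
        ]
        traj = make_traj(coords, rows)
        matrix = detect_hbonds(traj)
        expected = np.zeros(n_frames, dtype=int)
        for f in range(n_frames):
            da = coords[f, 2] - coords[f, 0]
            dh = coords[f, 1] - coords[f, 0]
            dist = np.linalg.norm(da)
            cosang = da @ dh / (np.linalg.norm(da) * np.linalg.norm(dh))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            expected[f] = int(dist <= 3.5 and ang <= 30.0)
        got = matrix.existence[0] if matrix.bonds else np.zeros(n_frames, dtype=int)
        assert np.array_equal(got, expected)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(22)
        coords = np.zeros((50, 3, 3))
        coords[:, 0] = rng.normal(scale=1.0, size=(50, 3))
        coords[:, 1] = coords[:, 0] + rng.normal(scale=0.5, size=(50, 3))
        coords[:, 2] = rng.normal(scale=1.5, size=(50, 3))
        rows = [
            atom_row(0, 99, chain="X", donor=True, ligand=True),
            atom_row(1, 99, chain="X", ligand=True, parent=0),
            atom_row(2, 7, acceptor=True),
        ]
        traj = make_traj(coords, rows)
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7])
        moved = make_traj(rot.apply(coords.reshape(-1, 3)).reshape(coords.shape) + 100.0, rows)
        assert np.array_equal(detect_hbonds(traj).existence, detect_hbonds(moved).existence)

    def test_donor_without_hydrogen_errors(self):
        coords = np.zeros((1, 2, 3))
        rows = [atom_row(0, 99, chain="X", donor=True, ligand=True),
                atom_row(1, 7, acceptor=True)]
        with pytest.raises(ValueError, match="no attached hydrogen"):
            detect_hbonds(make_traj(coords, rows))


def make_hbond_matrix(existence, partners):
    bonds = [
        HBond(donor_atom=100 + i, hydrogen_atom=200 + i, acceptor_atom=i,
              donor_residue="X:LIG:1", acceptor_residue=p, partner_residue=p)
        for i, p in enumerate(partners)
    ]
    return HBondMatrix(bonds, np.asarray(existence, dtype=np.uint8))


class TestOccupancyStats:
    def test_all_zero_matrix(self):
        stats = occupancy_stats(make_hbond_matrix(np.zeros((2, 10)), ["A:SER:1", "A:THR:2"]))
        assert all(v == 0.0 for v in stats.per_residue.values())
        assert stats.frac_at_least_one == stats.frac_at_least_two == 0.0

    def test_hand_counted_occupancy(self):
        existence = np.zeros((1, 10))
        existence[0, [0, 3, 5, 8]] = 1
        stats = occupancy_stats(make_hbond_matrix(existence, ["A:SER:1"]))
        assert stats.per_residue["A:SER:1"] == 0.4

    def test_simultaneity_hand_count(self):
        # both residues bonded in frames 0-2; residue 1 alone in frames 3-6
        existence = np.zeros((2, 10))
        existence[0, :7] = 1
        existence[1, :3] = 1
        stats = occupancy_stats(make_hbond_matrix(existence, ["A:SER:1", "A:THR:2"]))
        assert stats.frac_at_least_one == pytest.approx(0.7)
        assert stats.frac_at_least_two == pytest.approx(0.3)

    def test_two_bonds_same_residue_not_simultaneous(self):
        existence = np.ones((2, 4))
        stats = occupancy_stats(make_hbond_matrix(existence, ["A:SER:1", "A:SER:1"]))
        assert stats.frac_at_least_one == 1.0
        assert stats.frac_at_least_two == 0.0  # distinct residues required

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        existence = rng.integers(0, 2, (4, 50))
        stats = occupancy_stats(
            make_hbond_matrix(existence, ["A:A:1", "A:B:2", "A:C:3", "A:D:4"]))
        assert stats.frac_at_least_two <= stats.frac_at_least_one <= 1.0


class TestBinnedCounts:
    def test_all_zero(self):
        m = make_hbond_matrix(np.zeros((1, 1000)), ["A:SER:1"])
        m.times = np.arange(1000) * 10.0
        df = binned_hbond_counts(m, bin_width_ns=1.0)
        assert (df["count"] == 0).all() and (df["category"] == "<10").all()

    def test_fully_bonded_10ns_bins(self):
        n = 10_000  # 100 ns at 10 ps spacing
        m = make_hbond_matrix(np.ones((1, n)), ["A:SER:1"])
        m.times = np.arange(n) * 10.0
        df = binned_hbond_counts(m, bin_width_ns=10.0)
        assert len(df) == 10
        assert (df["count"] == 1000).all() and (df["category"] == ">20").all()

    def test_category_boundaries_inclusive_middle(self):
        existence = np.zeros((3, 3000))
        existence[0, :9] = 1    # 9 -> "<10"
        existence[1, :10] = 1   # 10 -> "10-20"
        existence[2, :21] = 1   # 21 -> ">20"
        m = make_hbond_matrix(existence, ["A:A:1", "A:B:2", "A:C:3"])
        m.times = np.arange(3000) * 10.0
        df = binned_hbond_counts(m, bin_width_ns=30.0).set_index("residue")
        assert df.loc["A:A:1", "category"] == "<10"
        assert df.loc["A:B:2", "category"] == "10-20"
        assert df.loc["A:C:3", "category"] == ">20"

    def test_counts_conserved(self):
        rng = np.random.default_rng(8)
        existence = rng.integers(0, 2, (2, 2000))
        m = make_hbond_matrix(existence, ["A:A:1", "A:B:2"])
        m.times = np.arange(2000) * 10.0
        df = binned_hbond_counts(m, bin_width_ns=5.0)
        per_res_bonded = {"A:A:1": existence[0].sum(), "A:B:2": existence[1].sum()}
        for res, total in per_res_bonded.items():
            assert df.loc[df["residue"] == res, "count"].sum() == total

    def test_bin_smaller_than_spacing_errors(self):
        m = make_hbond_matrix(np.ones((1, 100)), ["A:A:1"])
        m.times = np.arange(100) * 10.0
        with pytest.raises(ValueError):
            binned_hbond_counts(m, bin_width_ns=0.001)
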