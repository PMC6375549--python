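"""Trajectory observables: MSD, unwrapping, S_CD, RDF, hydration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotorflim.md import (
    DistanceBins,
    assign_leaflet,
    first_shell_cutoff,
    hydration_counts,
    msd_xy,
    order_parameter,
    rdf,
    unwrap,
    RDFResult,
)
from rotorflim.synthetic import (
    TrajectorySpec,
    generate_brownian_trajectory,
    generate_toy_bilayer,
)
from rotorflim.trajectory import Trajectory, write_gro, read_gro


def brute_force_msd_xy(coords_xy, origins, max_lag):
    """Oracle: explicit double loop over origins, atoms and lags."""
    n_frames, n_atoms, _ = coords_xy.shape
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for o in origins:
        for lag in range(max_lag + 1):
            if o + lag >= n_frames:
                break
            for a in range(n_atoms):
                dx = coords_xy[o + lag, a, 0] - coords_xy[o, a, 0]
                dy = coords_xy[o + lag, a, 1] - coords_xy[o, a, 1]
                sums[lag] += dx * dx + dy * dy
                counts[lag] += 1
    return sums / counts


class TestMsd:
    def test_static_trajectory_msd_is_zero(self):
        spec = TrajectorySpec(n_atoms=5, diffusion_nm2_per_ps=0.0, n_frames=40)
        res = msd_xy(generate_brownian_trajectory(spec), "diffusing")
        np.testing.assert_array_equal(res.msd_nm2, 0.0)

    def test_matches_brute_force_oracle_exactly(self, rng):
        coords = rng.normal(size=(10, 4, 3))
        traj = Trajectory(coords=coords, box=np.full(3, 100.0), dt_ps=1.0,
                          is_wrapped=False)
        res = msd_xy(traj, "all", origin_stride=3)
        want = brute_force_msd_xy(coords[:, :, :2], origins=[0, 3, 6], max_lag=9)
        np.testing.assert_allclose(res.msd_nm2, want, atol=1e-12)

    def test_einstein_relation_recovers_diffusion(self, brownian_traj):
        spec, traj = brownian_traj
        res = msd_xy(traj, "diffusing", origin_stride=25)
        d_fit, _ = res.fit_diffusion()
        assert d_fit == pytest.approx(spec.diffusion_nm2_per_ps, rel=0.10)

    def test_single_origin_is_special_case_of_multi(self, rng):
        coords = rng.normal(size=(20, 3, 3))
        traj = Trajectory(coords=coords, box=np.full(3, 100.0), dt_ps=1.0,
                          is_wrapped=False)
        single = msd_xy(traj, "all", origin_stride=None)
        want = brute_force_msd_xy(coords[:, :, :2], origins=[0], max_lag=19)
        np.testing.assert_allclose(single.msd_nm2, want, atol=1e-12)

    def test_wrapped_only_trajectory_rejected_with_guidance(self):
        traj = Trajectory(coords=np.zeros((5, 2, 3)) + 0.5,
                          box=np.ones(3), dt_ps=1.0, is_wrapped=True)
        with pytest.raises(ValueError, match="unwrap"):
            msd_xy(traj, "all")

    def test_msd_zero_at_lag_zero(self, brownian_traj):
        _, traj = brownian_traj
        res = msd_xy(traj, "diffusing", origin_stride=100)
        assert res.msd_nm2[0] == 0.0


class TestUnwrap:
    def test_identity_without_boundary_crossings(self):
        coords = np.cumsum(np.full((10, 2, 3), 0.01), axis=0) + 2.0
        traj = Trajectory(coords=coords, box=np.full(3, 10.0), dt_ps=1.0)
        out = unwrap(traj)
        np.testing.assert_allclose(out.unwrapped, coords, atol=1e-12)

    def test_crossing_plus_x_boundary_keeps_monotone_x(self):
        x = np.linspace(9.5, 10.6, 12) % 10.0
        coords = np.zeros((12, 1, 3)) + 5.0
        coords[:, 0, 0] = x
        traj = Trajectory(coords=coords, box=np.full(3, 10.0), dt_ps=1.0)
        out = unwrap(traj)
        assert np.all(np.diff(out.unwrapped[:, 0, 0]) > 0)

    def test_rewrapping_recovers_originals(self, brownian_traj):
        _, traj = brownian_traj
        rewrapped = np.mod(traj.unwrapped, traj.box)
        np.testing.assert_allclose(rewrapped, traj.coords, atol=1e-9)

    def test_near_half_box_jump_warns(self):
        coords = np.zeros((3, 1, 3)) + 1.0
        coords[1, 0, 0] = 5.7  # 4.7 nm jump in a 10 nm box
        traj = Trajectory(coords=coords, box=np.full(3, 10.0), dt_ps=1.0)
        with pytest.warns(UserWarning, match="undersampled"):
            unwrap(traj)


class TestOrderParameter:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.0, 1.0), (90.0, -0.5), (180.0, 1.0)],
    )
    def test_analytic_limits_exact(self, beta, expected):
        tb = generate_toy_bilayer(beta_deg=beta, n_per_leaflet=4)
        prof = order_parameter(tb.trajectory, tb.topology)
        np.testing.assert_allclose(prof["scd_mean"], expected, atol=1e-12)

    def test_magic_angle_vanishes(self):
        tb = generate_toy_bilayer(beta_deg=np.degrees(np.arccos(1 / np.sqrt(3))),
                                  n_per_leaflet=4)
        prof = order_parameter(tb.trajectory, tb.topology)
        assert np.max(np.abs(prof["scd_mean"])) < 1e-4

    @settings(derandomize=True, max_examples=20)
    @given(beta=st.floats(0.0, 180.0))
    def test_bounded_for_any_angle(self, beta):
        tb = generate_toy_bilayer(beta_deg=beta, n_per_leaflet=1, n_carbons=1)
        prof = order_parameter(tb.trajectory, tb.topology)
        assert np.all(prof["scd_mean"] >= -0.5 - 1e-12)
        assert np.all(prof["scd_mean"] <= 1.0 + 1e-12)

    def test_isotropic_bonds_average_to_zero(self, rng):
        # 10^4 random C-H orientations: mean S_CD within 3 standard errors of 0
        n = 10_000
        u = rng.uniform(-1.0, 1.0, n)  # cos(beta) uniform for isotropic bonds
        scd = 0.5 * (3.0 * u**2 - 1.0)
        se = scd.std(ddof=1) / np.sqrt(n)
        assert abs(scd.mean()) < 3.0 * se

    def test_long_form_profile_is_grouped_by_chain_and_bin(self, toy_bilayer):
        prof = order_parameter(toy_bilayer.trajectory, toy_bilayer.topology)
        assert set(prof["chain"]) == {"sn1", "sn2"}
        assert set(prof["leaflet"]) <= {"same", "opposite"}
        total = prof.groupby(["chain", "carbon_index"])["n_samples"].sum()
        # every lipid contributes each carbon exactly once per frame
        assert (total == toy_bilayer.topology.n_lipids).all()


class TestLeaflets:
    def test_same_and_opposite_assignment(self, toy_bilayer):
        leaf = assign_leaflet(toy_bilayer.trajectory, toy_bilayer.topology)
        n = toy_bilayer.topology.n_lipids
        assert (leaf == "same").sum() == n // 2
        assert (leaf == "opposite").sum() == n // 2

    def test_probe_required(self, toy_bilayer):
        tb = generate_toy_bilayer(include_probe=False, n_per_leaflet=2)
        with pytest.raises(ValueError, match="probe"):
            assign_leaflet(tb.trajectory, tb.topology)


class TestDistanceBins:
    def test_default_edges_make_five_bins(self):
        bins = DistanceBins()
        assert bins.n_bins == 5
        assert bins.edges == (0.7, 1.0, 1.6, 2.0)

    def test_assignment_is_a_partition(self, rng):
        bins = DistanceBins()
        d = rng.uniform(0.0, 3.0, 500)
        idx = bins.assign(d)
        assert idx.min() >= 0 and idx.max() < bins.n_bins
        # boundary membership: closed on the left
        assert bins.assign(0.7) == 1
        assert bins.assign(0.7 - 1e-12) == 0

    def test_bin_populations_sum_to_lipid_count(self, toy_bilayer):
        prof = order_parameter(toy_bilayer.trajectory, toy_bilayer.topology)
        one_carbon = prof[(prof["chain"] == "sn1") & (prof["carbon_index"] == 1)]
        assert one_carbon["n_samples"].sum() == toy_bilayer.topology.n_lipids


class TestRdf:
    def test_ideal_gas_is_flat_beyond_excluded_volume(self):
        rng = np.random.default_rng(7)
        box = np.full(3, 8.0)
        coords = rng.uniform(0, 8.0, size=(8, 220, 3))  # ~1.7e5 pairs in shells
        traj = Trajectory(coords=coords, box=box, dt_ps=1.0,
                          roles={"a": list(range(110)),
                                 "b": list(range(110, 220))})
        res = rdf(traj, "a", "b", r_max=3.0, dr=0.25)
        sel = res.r_nm > 1.0  # enough pairs per shell out here
        np.testing.assert_allclose(res.g[sel], 1.0, atol=0.05)

    def test_single_pair_peaks_in_its_bin(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [0.42, 0.0, 0.0]
        traj = Trajectory(coords=coords + 2.0, box=np.full(3, 6.0), dt_ps=1.0,
                          roles={"c": [0], "p": [1]})
        res = rdf(traj, "c", "p", r_max=1.0, dr=0.05)
        assert res.counts.sum() == 1
        assert res.counts[np.digitize(0.42, np.arange(0, 1.05, 0.05)) - 1] == 1

    def test_r_max_beyond_half_box_rejected(self, toy_bilayer):
        traj = toy_bilayer.trajectory
        with pytest.raises(ValueError, match="half"):
            rdf(traj, np.array([0]), np.array([1]), r_max=traj.box.min())

    def test_empty_selection_rejected(self, toy_bilayer):
        with pytest.raises((ValueError, KeyError)):
            rdf(toy_bilayer.trajectory, np.array([], dtype=int),
                np.array([1]), r_max=1.0)


class TestFirstShellCutoff:
    @staticmethod
    def synthetic_gr(peak=0.35, trough=0.52):
        r = np.arange(0.025, 1.0, 0.05)
        g = (1.0
             + 1.6 * np.exp(-0.5 * ((r - peak) / 0.05) ** 2)
             - 0.7 * np.exp(-0.5 * ((r - trough) / 0.05) ** 2))
        g[r < 0.25] = 0.0
        return RDFResult(r, g, np.zeros_like(r), 0.05)

    def test_finds_constructed_minimum(self):
        res = self.synthetic_gr()
        cut = first_shell_cutoff(res)
        assert cut == pytest.approx(0.52, abs=0.05)

    def test_flat_profile_flagged(self):
        r = np.arange(0.025, 1.0, 0.05)
        res = RDFResult(r, np.ones_like(r), np.zeros_like(r), 0.05)
        with pytest.warns(UserWarning, match="no cutoff"):
            assert first_shell_cutoff(res) is None

    def test_window_one_equals_raw_argrelmin(self):
        res = self.synthetic_gr()
        assert first_shell_cutoff(res, smooth_window=1) == pytest.approx(
            0.52, abs=0.05
        )


class TestHydration:
    def test_constructed_shell_counts_exact(self, toy_bilayer):
        cutoffs = {"onium": 0.3, "phosphate": 0.3, "ester": 0.3}
        table = hydration_counts(toy_bilayer.trajectory, toy_bilayer.topology,
                                 cutoffs)
        sampled = table.data[table.data["n"] > 0]
        for grp, want in toy_bilayer.expected_shell_counts.items():
            got = sampled.loc[sampled["group"] == grp, "mean"]
            np.testing.assert_allclose(got, want)
            np.testing.assert_allclose(
                sampled.loc[sampled["group"] == grp, "sd"], 0.0
            )

    def test_table_has_full_3x2x5_shape(self, toy_bilayer):
        cutoffs = {"onium": 0.3, "phosphate": 0.3, "ester": 0.3}
        table = hydration_counts(toy_bilayer.trajectory, toy_bilayer.topology,
                                 cutoffs)
        assert len(table.data) == 3 * 2 * 5
        wide = table.wide()
        assert wide.shape == (5, 6)

    def test_no_waters_gives_all_zero_counts(self):
        tb = generate_toy_bilayer(
            n_per_leaflet=2,
            waters_per_group={"onium": 0, "phosphate": 0, "ester": 0},
        )
        # topology then has no water oxygens at all
        with pytest.raises(ValueError, match="water"):
            hydration_counts(tb.trajectory, tb.topology,
                             {"onium": 0.3, "phosphate": 0.3, "ester": 0.3})

    def test_missing_cutoff_rejected(self, toy_bilayer):
        with pytest.raises(ValueError, match="missing cutoff"):
            hydration_counts(toy_bilayer.trajectory, toy_bilayer.topology,
                             {"onium": 0.3})

    def test_doubling_cutoff_scales_count_with_volume(self):
        # uniform water bath: count within r grows ~ r^3 (factor 8 for 2r)
        rng = np.random.default_rng(11)
        box = np.full(3, 6.0)
        n_w = 50_000
        waters = rng.uniform(0, 6.0, size=(n_w, 3))
        from rotorflim.trajectory import BilayerTopology, LipidRecord

        lip = LipidRecord(phosphorus=0, onium=1, phosphate=(0,),
                          ester_oxygens=(2,))
        coords = np.vstack([[[3.0, 3.0, 3.0], [3.0, 3.0, 4.5],
                             [3.0, 3.0, 1.5]], waters])[None]
        topo = BilayerTopology([lip],
                               water_oxygens=list(range(3, 3 + n_w)))
        traj = Trajectory(coords=coords, box=box, dt_ps=1.0)
        small = hydration_counts(traj, topo,
                                 {"onium": 0.5, "phosphate": 0.5, "ester": 0.5})
        large = hydration_counts(traj, topo,
                                 {"onium": 1.0, "phosphate": 1.0, "ester": 1.0})
        s = small.data.loc[small.data["n"] > 0, "mean"].to_numpy()
        l = large.data.loc[large.data["n"] > 0, "mean"].to_numpy()
        assert np.mean(l / s) == pytest.approx(8.0, rel=0.10)


class TestGroRoundTrip:
    def test_trajectory_survives_gro_round_trip(self, tmp_path):
        spec = TrajectorySpec(n_atoms=6, n_frames=4, seed=3)
        traj = generate_brownian_trajectory(spec)
        path = tmp_path / "traj.gro"
        write_gro(traj, path)
        back = read_gro(path, dt_ps=spec.dt_ps)
        assert back.n_frames == 4 and back.n_atoms == 6
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)
        np.testing.assert_allclose(back.box, traj.box, atol=1e-4)

    def test_topology_json_round_trip(self, toy_bilayer, tmp_path):
        from rotorflim.trajectory import BilayerTopology

        path = tmp_path / "roles.json"
        toy_bilayer.topology.to_json(path)
        back = BilayerTopology.from_json(path)
        assert back.probe_atom == toy_bilayer.topology.probe_atom
        assert back.lipids == toy_bilayer.topology.lipids
        assert back.water_oxygens == toy_bilayer.topology.water_oxygens
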