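"""Analyzers: clustering vs brute force, profiles, thickness, SASA, packing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrisome.analysis import (NotABilayerError, SasaSeries,
                                 aggregate_metrics, bilayer_thickness,
                                 cluster_aggregates, core_thickness,
                                 density_profile, interdigitation_ratio,
                                 monomer_length, packing_parameter,
                                 sasa_plateau, shrake_rupley_sasa,
                                 tanford_chain_volume)
from dendrisome.structures import (BeadFrame, BilayerParams, REFERENCE_BILAYER,
                                   get_fixture, make_aggregate_box,
                                   make_bilayer_patch)
from .conftest import brute_force_clusters


def _random_frame(rng, n_mol, box):
    """Molecules of 1-4 beads thrown uniformly into the box."""
    coords, mols = [], []
    for m in range(n_mol):
        k = rng.integers(1, 5)
        center = rng.uniform(0, 1, 3) * box
        pts = center + rng.normal(0, 0.4, (k, 3))
        coords.append(pts % box)
        mols += [m] * k
    coords = np.concatenate(coords)
    n = len(coords)
    return BeadFrame(coords=coords, box=np.asarray(box, float),
                     molecule_id=np.array(mols),
                     bead_name=np.array(["TC"] * n, dtype=object),
                     group_class=np.array(["hydrophobic"] * n, dtype=object))


class TestClustering:
    def test_matches_brute_force_on_random_systems(self):
        """PBC single linkage equals the O(N^2) minimum-image oracle."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            n_mol = int(rng.integers(2, 60))
            frame = _random_frame(rng, n_mol, (8.0, 9.0, 10.0))
            got = cluster_aggregates(frame, 0.8, "all")
            expect = brute_force_clusters(frame, 0.8, "all")
            assert sorted(map(sorted, got.clusters)) == \
                sorted(map(sorted, expect))

    def test_recovers_generator_ground_truth(self):
        frame = make_aggregate_box([5, 7, 9], (30.0, 30.0, 30.0), 5.0, seed=1)
        rep = cluster_aggregates(frame, 0.6)
        assert sorted(rep.aggregation_numbers) == [5, 7, 9]
        labels = np.asarray(frame.ground_truth["cluster_of_molecule"])
        for cluster in rep.clusters:
            assert len(set(labels[cluster])) == 1

    def test_boundary_straddling_cluster_is_one(self):
        frame = make_aggregate_box([8], (12.0, 12.0, 12.0), 3.0, seed=2,
                                   centers=[(0.05, 6.0, 6.0)])
        assert cluster_aggregates(frame, 0.6).n_clusters == 1

    def test_everything_within_cutoff_is_one_cluster(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(4.9, 5.1, (12, 3))
        frame = BeadFrame(coords=coords, box=(10.0, 10.0, 10.0),
                          molecule_id=np.arange(12),
                          bead_name=np.array(["TC"] * 12, dtype=object),
                          group_class=np.array(["hydrophobic"] * 12,
                                               dtype=object))
        rep = cluster_aggregates(frame, 0.6, "all")
        assert rep.aggregation_numbers == [12]

    def test_ambiguous_cutoff_rejected(self, reference_patch):
        with pytest.raises(ValueError, match="minimum image"):
            cluster_aggregates(reference_patch, 3.0)

    def test_metrics_closed_forms(self):
        # two beads distance d apart: Rg = d/2
        frame = BeadFrame(coords=[[1.0, 1, 1], [2.0, 1, 1]],
                          box=(10.0, 10.0, 10.0), molecule_id=[0, 1],
                          bead_name=np.array(["TC", "TC"], dtype=object),
                          group_class=np.array(["hydrophobic"] * 2,
                                               dtype=object))
        rep = aggregate_metrics(cluster_aggregates(frame, 1.5, "all"), frame)
        m = rep.metrics["per_cluster"][0]
        assert m["radius_of_gyration"] == pytest.approx(0.5)
        # single bead: degenerate, Rg = 0
        solo = BeadFrame(coords=[[5.0, 5, 5]], box=(10.0, 10.0, 10.0),
                         molecule_id=[0],
                         bead_name=np.array(["TC"], dtype=object),
                         group_class=np.array(["hydrophobic"], dtype=object))
        rep = aggregate_metrics(cluster_aggregates(solo, 0.6, "all"), solo)
        m = rep.metrics["per_cluster"][0]
        assert m["radius_of_gyration"] == 0.0
        assert m["degenerate"] is True

    def test_uniform_ball_rg_and_diameter(self):
        """Beads filling a sphere: Rg -> R sqrt(3/5), diameter -> 2R."""
        rng = np.random.default_rng(42)
        R = 3.0
        pts = rng.normal(size=(10_000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= R * rng.uniform(0, 1, 10_000)[:, None] ** (1 / 3)
        frame = BeadFrame(coords=pts + 10.0, box=(20.0, 20.0, 20.0),
                          molecule_id=np.zeros(len(pts), int),
                          bead_name=np.array(["TC"] * len(pts), dtype=object),
                          group_class=np.array(["hydrophobic"] * len(pts),
                                               dtype=object))
        rep = aggregate_metrics(cluster_aggregates(frame, 1.0, "all"), frame)
        m = rep.metrics["per_cluster"][0]
        assert m["radius_of_gyration"] == pytest.approx(R * np.sqrt(3 / 5),
                                                        rel=0.05)
        assert m["diameter"] == pytest.approx(2 * R, rel=0.05)
        assert m["hull_volume"] == pytest.approx(4 / 3 * np.pi * R**3, rel=0.05)


class TestDensityProfile:
    def test_conservation_on_every_fixture(self):
        for name in ("reference_patch", "interdigitated_patch",
                     "vesicle_small", "micelle_small", "aggregates_three"):
            frame = get_fixture(name)
            if frame.n_beads == 0:
                continue
            prof = density_profile(frame)
            for g, cnt in prof.counts.items():
                assert cnt.sum() == frame.select(g).sum()
                np.testing.assert_allclose(
                    prof.densities[g].sum() * prof.bin_volume, cnt.sum())

    def test_uniform_beads_within_binomial_bounds(self):
        rng = np.random.default_rng(99)
        n = 10_000
        coords = rng.uniform(0, 10, (n, 3))
        frame = BeadFrame(coords=coords, box=(10.0, 10.0, 10.0),
                          molecule_id=np.zeros(n, int),
                          bead_name=np.array(["TC"] * n, dtype=object),
                          group_class=np.array(["hydrophobic"] * n,
                                               dtype=object))
        prof = density_profile(frame, ["hydrophobic"], bin_width=0.5)
        counts = prof.counts["hydrophobic"]
        p = 0.5 / 10.0
        sigma = np.sqrt(n * p * (1 - p))
        assert np.abs(counts - n * p).max() <= 4 * sigma

    def test_reference_patch_profile_shape(self, reference_patch):
        """Heads bimodal at the leaflet planes; hydrophobic peak central."""
        prof = density_profile(reference_patch, bin_width=0.1)
        mid = reference_patch.ground_truth["midplane_z"]
        heads = prof.densities["polar_head"]
        hphob = prof.densities["hydrophobic_total"]
        z = prof.centers - mid
        # two dominant head peaks near +/- 2.05
        order = np.argsort(heads)[::-1]
        top2 = np.sort(z[order[:2]])
        assert top2[0] == pytest.approx(-2.05, abs=0.1)
        assert top2[1] == pytest.approx(+2.05, abs=0.1)
        # hydrophobic density maximal near the bilayer center
        assert abs(z[np.argmax(hphob)]) <= 0.3
        # and hydrophilic total depleted at the center relative to its peaks
        phil = prof.densities["hydrophilic_total"]
        assert phil[np.argmin(np.abs(z))] < phil.max() / 2

    def test_empty_group_and_bad_region(self, reference_patch):
        prof = density_profile(reference_patch, [])
        assert prof.densities == {}
        with pytest.raises(ValueError):
            density_profile(reference_patch, region=(5.0, 5.0))
        with pytest.raises(ValueError):
            density_profile(reference_patch, bin_width=0.0)


class TestThickness:
    def test_two_delta_leaflets_exact(self):
        n = 200
        z = np.r_[np.full(n, 4.0), np.full(n, 6.0)] + 0.05  # bin centers
        coords = np.column_stack([np.random.default_rng(0).uniform(0, 5, 2 * n),
                                  np.random.default_rng(1).uniform(0, 5, 2 * n),
                                  z])
        frame = BeadFrame(coords=coords, box=(5.0, 5.0, 10.0),
                          molecule_id=np.zeros(2 * n, int),
                          bead_name=np.array(["OH1"] * 2 * n, dtype=object),
                          group_class=np.array(["polar_head"] * 2 * n,
                                               dtype=object))
        prof = density_profile(frame, ["polar_head"], bin_width=0.1)
        assert bilayer_thickness(prof) == pytest.approx(2.0, abs=1e-6)

    def test_recovery_across_geometry_and_noise_sweep(self):
        """Estimators recover construction within a bin across the sweep."""
        for d_hh in (3.0, 4.1, 5.0):
            for sigma in (0.0, 0.05, 0.1):
                L = (d_hh - 0.1) / 2
                p = BilayerParams(d_hh, 0.44 * d_hh, L, 0.35 * L, 1.1,
                                  (6.5, 5.4), sigma, seed=1)
                frame = make_bilayer_patch(p)
                prof = density_profile(frame, bin_width=0.1)
                assert bilayer_thickness(prof) == pytest.approx(d_hh, abs=0.1)
                assert core_thickness(prof) == pytest.approx(0.44 * d_hh,
                                                             abs=0.1)
                Lm, ltm = monomer_length(frame)
                assert Lm == pytest.approx(L, abs=0.1)
                assert ltm == pytest.approx(0.35 * L, abs=0.1)

    def test_micelle_profile_is_not_a_bilayer(self):
        frame = get_fixture("micelle_small")
        prof = density_profile(frame, ["polar_head"], bin_width=0.4)
        with pytest.raises(NotABilayerError):
            bilayer_thickness(prof)

    def test_core_fwhm_of_rectangular_slab(self):
        rng = np.random.default_rng(3)
        n = 5000
        coords = np.column_stack([rng.uniform(0, 5, n), rng.uniform(0, 5, n),
                                  rng.uniform(4.0, 6.5, n)])
        frame = BeadFrame(coords=coords, box=(5.0, 5.0, 10.0),
                          molecule_id=np.zeros(n, int),
                          bead_name=np.array(["T1A"] * n, dtype=object),
                          group_class=np.array(["hydrophobic"] * n,
                                               dtype=object))
        prof = density_profile(frame, ["hydrophobic_total"], bin_width=0.1)
        assert core_thickness(prof) == pytest.approx(2.5, abs=0.1)

    def test_zero_hydrophobic_density_rejected(self):
        frame = get_fixture("micelle_small")
        prof = density_profile(frame, ["hydrophobic_total"], region=(0.0, 0.5))
        with pytest.raises(ValueError):
            core_thickness(prof)


class TestLengthsAndInterdigitation:
    def test_rigid_rod_exact_length(self, janus_topology):
        from dendrisome.structures import _molecule_template

        xyz = _molecule_template(janus_topology, 4.1, 2.0, 0.7, 1.8)
        n = janus_topology.n_beads
        frame = BeadFrame(coords=xyz + 5.0, box=(10.0, 10.0, 10.0),
                          molecule_id=np.zeros(n, int),
                          bead_name=np.array([b.name for b in
                                              janus_topology.beads],
                                             dtype=object),
                          group_class=np.array([b.group_class.value for b in
                                                janus_topology.beads],
                                               dtype=object))
        L, lt = monomer_length(frame)
        assert lt == pytest.approx(0.7, abs=1e-9)
        assert L == pytest.approx(2.0, abs=2e-3)

    def test_coincident_beads_give_zero(self):
        frame = BeadFrame(coords=np.zeros((3, 3)) + 5.0,
                          box=(10.0, 10.0, 10.0),
                          molecule_id=[0, 0, 0],
                          bead_name=np.array(["OH1", "T1A", "T1C"],
                                             dtype=object),
                          group_class=np.array(["polar_head", "hydrophobic",
                                                "tail_end"], dtype=object))
        assert monomer_length(frame) == (0.0, 0.0)

    def test_reference_values_classify_as_non_interdigitated(self):
        ratio, label = interdigitation_ratio(4.1, 2.0)
        assert ratio == pytest.approx(1.025)
        assert label == "non_interdigitated"
        assert interdigitation_ratio(4.0, 2.0)[1] == "boundary"
        assert interdigitation_ratio(3.0, 2.0)[1] == "interdigitated"

    def test_monotone_in_thickness_across_fixtures(self):
        """Non-interdigitated fixtures give ratio > 1, overlapped ones < 1."""
        for d_hh, interdig in ((4.1, False), (4.6, False), (5.0, False),
                               (3.0, True), (3.4, True)):
            L = 2.0 if interdig else (d_hh - 0.1) / 2
            lt = 0.7 if interdig else 0.35 * L
            p = BilayerParams(d_hh, 1.8 if interdig else 0.44 * d_hh, L, lt,
                              1.1, (6.5, 5.4), 0.05,
                              interdigitated=interdig, seed=2)
            frame = make_bilayer_patch(p)
            prof = density_profile(frame, bin_width=0.1)
            ratio, _ = interdigitation_ratio(bilayer_thickness(prof),
                                             monomer_length(frame)[0])
            assert (ratio > 1.0) == (not interdig)


class TestSasa:
    def test_single_sphere_analytic(self):
        total, _ = shrake_rupley_sasa([[0.0, 0, 0]], [0.47], probe=0.0)
        assert total == pytest.approx(4 * np.pi * 0.47**2, rel=1e-12)

    def test_coincident_spheres_count_once(self):
        total, _ = shrake_rupley_sasa([[0.0, 0, 0], [0.0, 0, 0]],
                                      [0.47, 0.47], probe=0.0)
        assert total == pytest.approx(4 * np.pi * 0.47**2, rel=1e-12)

    def test_two_sphere_closed_form(self):
        """Overlapping pair vs the spherical-cap formula, within 2%."""
        r, probe = 0.235, 0.264
        R = r + probe
        for d in (0.3, 0.5, 0.7, 0.9):
            expect = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2))
            total, _ = shrake_rupley_sasa([[0.0, 0, 0], [d, 0, 0]], [r, r],
                                          probe=probe, n_points=960)
            assert total == pytest.approx(expect, rel=0.02)

    def test_separated_spheres_additive(self):
        total, per = shrake_rupley_sasa([[0.0, 0, 0], [5.0, 0, 0]],
                                        [0.2, 0.3], probe=0.1)
        assert per[0] == pytest.approx(4 * np.pi * 0.3**2, rel=1e-12)
        assert per[1] == pytest.approx(4 * np.pi * 0.4**2, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([[0.0, 0, 0]], [0.2, 0.3])
        with pytest.raises(ValueError):
            shrake_rupley_sasa([[0.0, 0, 0]], [0.2], n_points=50)


class TestPlateau:
    def test_constant_series_plateaus_immediately(self):
        s = SasaSeries(np.arange(50.0), np.full(50, 7.0))
        assert sasa_plateau(s) == 0.0

    def test_linear_series_never_converges(self):
        t = np.arange(100.0)
        assert sasa_plateau(SasaSeries(t, 2.0 * t + 5.0)) is None

    def test_exponential_relaxation_detected_after_a_few_tau(self):
        t = np.arange(0.0, 200.0)
        tau = 12.0
        rng = np.random.default_rng(11)
        y = 40.0 * np.exp(-t / tau) + 150.0 + rng.normal(0, 0.4, len(t))
        window = len(t) // 10
        t_eq = sasa_plateau(SasaSeries(t, y), window=window)
        assert t_eq is not None
        # the fitted slope reflects the window midpoint
        assert 3 * tau <= t_eq + window / 2 <= 6 * tau

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sasa_plateau(SasaSeries(np.arange(4.0), np.ones(4)), window=3)


class TestPackingParameter:
    def test_boundary_value(self):
        pp = packing_parameter(0.3, 0.6, 1.5)
        assert pp.p == pytest.approx(1 / 3)
        assert pp.shape_class == "boundary"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0),
           st.floats(0.1, 5.0))
    def test_homogeneous_in_chain_volume(self, v, a0, lc, alpha):
        p1 = packing_parameter(v, a0, lc).p
        p2 = packing_parameter(alpha * v, a0, lc).p
        assert p2 == pytest.approx(alpha * p1, rel=1e-9)

    def test_four_myristoyl_tails_cannot_make_spherical_micelles(self):
        """Tanford volume of 4 C13 chains with the measured tail length."""
        v = tanford_chain_volume(13, n_chains=4)
        for a0 in (0.8, 1.2, 1.6, 2.0):
            pp = packing_parameter(v, a0, 0.7)
            assert pp.p >= 1 / 3
            assert pp.shape_class != "spherical_micelle"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            packing_parameter(0.0, 1.0, 1.0)
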