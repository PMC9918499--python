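import numpy as np
import pytest

import nucdyn as nd
from nucdyn.geometry import radius_of_gyration
from nucdyn.model import CORE_HALF_SPAN
from nucdyn.synth import _Geometry


class TestBpCenter:
    def test_pseudo_atom_bead_returned(self, clean_sim):
        _, system, _, _ = clean_sim
        idx = system.bp_center_atoms(0)
        expected = system.reference_coordinates[idx].mean(axis=0)
        assert np.allclose(nd.bp_center(system.reference_coordinates, system, 0),
                           expected)

    def test_midpoint_of_constructed_pair(self, clean_sim):
        """With two center-defining atoms the bp center is their midpoint."""
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates.copy()
        idx = system.bp_center_atoms(10)
        a = coords[idx][0]
        assert np.allclose(nd.bp_center(coords, system, 10), a)
        # hand-check on raw vectors
        assert np.allclose((np.array([0., 0, 0]) + np.array([2., 0, 0])) / 2,
                           [1.0, 0, 0])

    def test_unknown_bp_rejected(self, clean_sim):
        _, system, _, _ = clean_sim
        with pytest.raises(ValueError):
            system.bp_center_atoms(200)


class TestCountUnwrapped:
    def test_reference_frame_zero(self, clean_sim):
        _, system, _, _ = clean_sim
        assert nd.count_unwrapped(system.reference_coordinates, system) == (0, 0)

    def test_entry_side_block_displacement(self, clean_sim):
        params, system, _, _ = clean_sim
        geo = _Geometry(params)
        coords = system.reference_coordinates.copy()
        coords[geo.entry_core_atoms[:5]] += 10.0 * geo.dna_radial[
            geo.entry_core_atoms[:5]]
        assert nd.count_unwrapped(coords, system) == (5, 0)

    def test_isolated_dyad_displacement_does_not_count(self, clean_sim):
        """End-anchored counting: an interior excursion is not unwrapping."""
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates.copy()
        idx = system.bp_center_atoms(0)
        coords[idx] += np.array([10.0, 0.0, 0.0])
        assert nd.count_unwrapped(coords, system) == (0, 0)

    def test_monotone_in_threshold(self, noisy_sim):
        _, system, ens, _ = noisy_sim
        f = ens.coordinates[7]
        lo = nd.count_unwrapped(f, system, threshold=5.0)
        hi = nd.count_unwrapped(f, system, threshold=9.0)
        assert hi[0] <= lo[0] and hi[1] <= lo[1]

    def test_unsuperposed_rejected(self, clean_sim):
        _, system, ens, _ = clean_sim
        with pytest.raises(ValueError):
            nd.count_unwrapped(ens.coordinates[0], system, superposed=False)
        unsup = nd.Ensemble(ens.coordinates[:3], ens.times[:3],
                            ens.sampling_interval)
        with pytest.raises(ValueError):
            nd.unwrap_series(unsup, system)

    def test_side_counts_bounded(self, clean_sim):
        _, system, ens, _ = clean_sim
        uw = nd.unwrap_series(ens, system)
        assert np.all(uw.total == uw.entry + uw.exit)
        assert uw.entry.max() <= CORE_HALF_SPAN


class TestRadiusOfGyration:
    def test_single_point_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), [0]) == 0.0

    def test_two_points_closed_form(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, [0, 1]) == pytest.approx(1.0)

    def test_uniform_ring_closed_form(self):
        theta = 2 * np.pi * np.arange(1000) / 1000
        r = 7.5
        coords = np.stack([r * np.cos(theta), r * np.sin(theta),
                           np.zeros_like(theta)], axis=1)
        got = radius_of_gyration(coords, np.arange(1000), mass_weighted=False)
        assert got == pytest.approx(r, abs=1e-9)

    def test_matches_two_pass_oracle(self, rng):
        coords = rng.normal(size=(50, 3)) * 4
        masses = rng.uniform(1, 12, size=50)
        sel = np.arange(50)
        w = masses / masses.sum()
        com = (w[:, None] * coords).sum(axis=0)
        oracle = np.sqrt(np.sum(w * np.sum((coords - com) ** 2, axis=1)))
        got = radius_of_gyration(coords, sel, masses=masses)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), [])


class TestGapingDistance:
    def test_constructed_separation(self, clean_sim):
        """Shifting one window's beads to a known centroid separation."""
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates.copy()
        d0 = nd.gaping_distance(coords, system)
        assert d0 > 0

    def test_axial_shift_pythagoras(self, clean_sim):
        params, system, _, _ = clean_sim
        geo = _Geometry(params)
        coords = system.reference_coordinates.copy()
        d0 = nd.gaping_distance(coords, system)
        inplane = geo.gape_inplane
        z0 = geo.gape_z0
        coords[geo.plus_half_atoms, 2] += 12.0 * geo.gape_sign
        d1 = nd.gaping_distance(coords, system)
        assert d0 == pytest.approx(np.hypot(inplane, z0), abs=1e-9)
        assert d1 == pytest.approx(np.hypot(inplane, z0 + 12.0), abs=1e-9)

    def test_rigid_transform_invariance(self, clean_sim):
        from scipy.spatial.transform import Rotation
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates
        R = Rotation.from_rotvec([0.4, -1.0, 0.2]).as_matrix()
        moved = coords @ R.T + np.array([5.0, 6.0, -7.0])
        assert nd.gaping_distance(moved, system) == pytest.approx(
            nd.gaping_distance(coords, system), abs=1e-9)

    def test_window_outside_core_rejected(self, clean_sim):
        _, system, _, _ = clean_sim
        with pytest.raises(ValueError):
            nd.gaping_distance(system.reference_coordinates, system,
                               shl_pair=(-8, 8))


class TestProjection:
    def test_reference_traces_superhelix_radius(self, clean_sim):
        from nucdyn.geometry import reference_plane
        params, system, _, _ = clean_sim
        xy = nd.project_dna_2d(system.reference_coordinates, system)
        core = np.abs(system.dna.bp_index) <= CORE_HALF_SPAN
        # measure radii about the projected superhelix axis (z axis at x=y=0)
        origin, e1, e2 = reference_plane(system)
        axis_xy = np.array([-origin @ e1, -origin @ e2])
        radii = np.linalg.norm(xy[core] - axis_xy, axis=1)
        assert np.allclose(radii, params.superhelix_radius, atol=0.5)

    def test_axial_displacement_invisible(self, clean_sim):
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates.copy()
        xy0 = nd.project_dna_2d(coords, system)
        idx = system.bp_center_atoms(30)
        coords[idx] += np.array([0.0, 0.0, 15.0])  # along the superhelix axis
        xy1 = nd.project_dna_2d(coords, system)
        assert np.allclose(xy0, xy1, atol=1e-8)

    def test_unwrapped_bp_project_outward(self, clean_sim):
        _, system, ens, truth = clean_sim
        f = int(np.argmax(truth.entry_unwrapped))
        i = int(truth.entry_unwrapped[f])
        if i == 0:
            pytest.skip("no unwrapping event in this fixture stream")
        xy = nd.project_dna_2d(ens.coordinates[f], system)
        core_idx = system.dna.bp_index
        unwrapped = (core_idx >= -73) & (core_idx < -73 + i)
        wrapped = (np.abs(core_idx) <= 73) & ~unwrapped
        assert np.linalg.norm(xy[unwrapped], axis=1).min() > \
            np.median(np.linalg.norm(xy[wrapped], axis=1))
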