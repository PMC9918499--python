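import numpy as np
import pandas as pd
import pytest

import nucdyn as nd
from nucdyn.model import CORE_HALF_SPAN
from nucdyn.synth import _Geometry, zipper_stationary_law


class TestReference:
    def test_one_bead_per_bp(self):
        system = nd.generate_reference()
        assert len(system.dna_atoms(heavy_only=False)) == 187

    def test_core_beads_on_superhelix_radius(self):
        params = nd.SyntheticParams()
        system = nd.generate_reference(params)
        core = system.dna_atoms(bp_window=(-73, 73))
        r = np.linalg.norm(system.reference_coordinates[core][:, :2], axis=1)
        assert np.allclose(r, params.superhelix_radius, atol=1e-6)

    def test_reference_gaping_matches_closed_form(self):
        """The measured SHL +/-4 distance on the reference equals the value
        implied by the helix pitch and the windows' in-plane separation."""
        params = nd.SyntheticParams()
        system = nd.generate_reference(params)
        geo = _Geometry(params)
        closed_form = np.hypot(geo.gape_inplane, geo.gape_z0)
        measured = nd.gaping_distance(system.reference_coordinates, system)
        assert measured == pytest.approx(closed_form, abs=1e-9)
        # axial separation follows from pitch x (turn fraction between windows)
        turn_fraction = (2 * round(10.3 * 4)) / 146 * params.total_turns
        assert geo.gape_z0 == pytest.approx(
            params.superhelix_pitch * turn_fraction, abs=1e-9)


class TestZipper:
    def test_seeded_determinism(self):
        p = nd.SyntheticParams(n_frames=50, seed=9)
        _, e1, t1 = nd.simulate_trajectory(p)
        _, e2, t2 = nd.simulate_trajectory(nd.SyntheticParams(n_frames=50, seed=9))
        assert np.array_equal(e1.coordinates, e2.coordinates)
        assert np.array_equal(t1.entry_unwrapped, t2.entry_unwrapped)
        assert np.array_equal(t1.gaping_distance, t2.gaping_distance)

    def test_huge_epsilon_freezes_zipper(self):
        p = nd.SyntheticParams(epsilon=50.0, n_frames=2000, seed=4)
        entry, exit_ = nd.simulate_unwrap_counts(p)
        assert entry.max() == 0 and exit_.max() == 0

    def test_stationary_law_matches_exact_enumeration(self):
        """Empirical occupancy of the chain matches the closed-form geometric
        law within 3 standard errors."""
        p = nd.SyntheticParams(epsilon=0.5, n_frames=50_000, seed=7)
        entry, exit_ = nd.simulate_unwrap_counts(p)
        pooled = np.concatenate([entry, exit_])
        law = zipper_stationary_law(p.epsilon, p.temperature, p.max_unwrap)
        frac_open = np.mean(pooled >= 1)
        expected = 1.0 - law[0]
        # correlated samples: use a conservative effective sample size
        n_eff = pooled.size / 20
        se = np.sqrt(expected * (1 - expected) / n_eff)
        assert abs(frac_open - expected) < 3 * se

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            nd.simulate_trajectory(nd.SyntheticParams(n_frames=0))


class TestLabelRecovery:
    def test_noise_free_labels_exact(self, clean_sim):
        _, system, ens, truth = clean_sim
        uw = nd.unwrap_series(ens, system)
        assert np.array_equal(uw.entry, truth.entry_unwrapped)
        assert np.array_equal(uw.exit, truth.exit_unwrapped)

    def test_noisy_labels_mostly_recovered(self, noisy_sim):
        _, system, ens, truth = noisy_sim
        uw = nd.unwrap_series(nd.superpose(ens, system), system)
        agree = np.mean((uw.entry == truth.entry_unwrapped)
                        & (uw.exit == truth.exit_unwrapped))
        assert agree >= 0.99

    def test_gaping_mode_near_target(self):
        p = nd.SyntheticParams(n_frames=4000, seed=31)
        system, ens, truth = nd.simulate_trajectory(p)
        gp = nd.gaping_series(ens, system)
        h, edges = np.histogram(gp.distance, bins=np.arange(15.0, 45.0, 0.5))
        mode = 0.5 * (edges[np.argmax(h)] + edges[np.argmax(h) + 1])
        assert mode == pytest.approx(p.gaping_mean, abs=0.5)

    def test_bound_tail_contacts_and_unbound_zero(self, clean_sim):
        _, system, ens, truth = clean_sim
        label = "H2A.Z:1:C"
        cs = nd.tail_dna_contact_series(ens, system, ("H2A.Z", 1, "C"), "total")
        bound = truth.tail_bound[label]
        assert np.array_equal(cs.counts, truth.tail_contacts[label])
        assert np.all(cs.counts[~bound] == 0)
        assert np.all(cs.counts[bound] >= truth.bound_contact_floor[label])


class TestFixtureFiles:
    def test_truth_tsv_row_count(self, fixture_dir, clean_sim):
        params, _, _, _ = clean_sim
        df = pd.read_csv(fixture_dir["truth"], sep="\t")
        assert len(df) == params.n_frames

    def test_programmed_unwrap_recovered_from_files(self, tmp_path):
        """A frozen entry-side count survives the write/load cycle."""
        p = nd.SyntheticParams(n_frames=5, seed=1, noise_sigma=0.0, epsilon=50.0)
        system, ens, truth = nd.simulate_trajectory(p)
        # impose i = 5 on the entry side by displacing bp -73..-69 radially
        geo = _Geometry(p)
        ens.coordinates[:, geo.entry_core_atoms[:5], :] += \
            12.5 * geo.dna_radial[geo.entry_core_atoms[:5]][None]
        paths = nd.write_fixture(system, ens, tmp_path)
        sys2 = nd.load_structure(paths["structure"], paths["topology"])
        ens2 = nd.load_trajectory(paths["trajectory"], sys2, 100.0,
                                  structure_path=paths["structure"])
        uw = nd.unwrap_series(nd.superpose(ens2, sys2), sys2)
        assert np.all(uw.entry == 5) and np.all(uw.exit == 0)

    def test_analyses_match_in_memory_within_precision(self, fixture_dir, clean_sim):
        _, system, ens, _ = clean_sim
        sys2 = nd.load_structure(fixture_dir["structure"], fixture_dir["topology"])
        ens2 = nd.load_trajectory(fixture_dir["trajectory"], sys2, 100.0,
                                  structure_path=fixture_dir["structure"])
        g_mem = nd.gaping_series(ens, system).distance
        g_file = nd.gaping_series(ens2, sys2).distance
        assert np.allclose(g_mem, g_file, atol=0.05)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [{"superhelix_radius": -1.0},
                                    {"noise_sigma": -0.1},
                                    {"gaping_mean": 0.0},
                                    {"max_unwrap": 0}])
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            nd.SyntheticParams(**kw)

    def test_bad_bind_prob_rejected(self):
        with pytest.raises(ValueError):
            nd.SyntheticParams(tail_bind_prob=lambda i: 2.0 * np.ones_like(
                np.asarray(i, dtype=float)))
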