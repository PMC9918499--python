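import numpy as np
import pytest
from scipy.spatial.distance import cdist

import nucdyn as nd
from nucdyn.contacts import min_distance, smooth_series


def brute_force_contacts(a, b, cutoff=4.5):
    return int((cdist(a, b) < cutoff).sum())


class TestCountContacts:
    def test_strictly_less_than_cutoff(self):
        a = np.array([[0.0, 0, 0]])
        assert nd.count_contacts(a, np.array([[4.49, 0, 0]])) == 1
        assert nd.count_contacts(a, np.array([[4.50, 0, 0]])) == 0

    def test_empty_selection_zero(self):
        assert nd.count_contacts(np.empty((0, 3)), np.zeros((5, 3))) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, size=(200, 3))
        a, b = pts[:100], pts[100:]
        assert nd.count_contacts(a, b) == brute_force_contacts(a, b)

    def test_symmetric(self, rng):
        a = rng.uniform(0, 20, size=(40, 3))
        b = rng.uniform(0, 20, size=(60, 3))
        assert nd.count_contacts(a, b) == nd.count_contacts(b, a)

    def test_monotone_in_cutoff(self, rng):
        a = rng.uniform(0, 15, size=(50, 3))
        b = rng.uniform(0, 15, size=(50, 3))
        assert nd.count_contacts(a, b, cutoff=3.0) <= \
            nd.count_contacts(a, b, cutoff=4.5)


class TestTailContactSeries:
    def test_region_partition_identity(self, clean_sim):
        _, system, ens, _ = clean_sim
        tail = ("H2A.Z", 1, "C")
        total = nd.tail_dna_contact_series(ens, system, tail, "total").counts
        parts = sum(nd.tail_dna_contact_series(ens, system, tail, r).counts
                    for r in ("inner", "outer", "linker"))
        assert np.array_equal(total, parts)

    def test_overlapping_selections_rejected(self, clean_sim):
        _, system, ens, _ = clean_sim
        sel = system.dna_atoms()
        from nucdyn.contacts import contact_series
        with pytest.raises(ValueError, match="disjoint"):
            contact_series(ens, system, sel, sel)

    def test_empty_tail_rejected(self, clean_sim):
        _, system, _, _ = clean_sim
        with pytest.raises(ValueError):
            system.tail_atoms("H4", 1, "C")  # H4 has no C-tail


class TestSmoothing:
    def test_constant_series_unchanged(self):
        y = np.full(500, 3.7)
        out = smooth_series(y, window_ns=10, sampling_interval=100.0)
        assert np.allclose(out, y, atol=1e-10)

    def test_linear_series_reproduced(self):
        """A degree-1 filter reproduces degree-1 signals everywhere,
        including the shrinking-window edges."""
        y = 0.31 * np.arange(600) - 4.0
        out = smooth_series(y, window_ns=10, poly_order=1,
                            sampling_interval=100.0)
        assert np.allclose(out, y, atol=1e-8)

    def test_white_noise_variance_reduction(self, rng):
        """Interior variance of a moving least-squares line on white noise
        drops by the window size (101 points at 10 ns / 100 ps)."""
        y = rng.normal(size=40_000)
        out = smooth_series(y, window_ns=10, sampling_interval=100.0)
        interior = out[200:-200]
        ratio = np.var(interior) / np.var(y)
        assert ratio == pytest.approx(1 / 101, rel=0.15)

    def test_window_odd_point_count(self):
        # 10 ns at 100 ps spans 101 points; shorter series must be rejected
        with pytest.raises(ValueError):
            smooth_series(np.zeros(50), window_ns=10, sampling_interval=100.0)


class TestMinDistance:
    def test_constructed_distance(self, clean_sim):
        _, system, _, _ = clean_sim
        coords = system.reference_coordinates.copy()
        tail = system.tail_atoms("H2A.Z", 1, "C")
        window = system.dna_atoms(bp_window=(-75, -41))
        target = coords[window[0]] + np.array([4.1, 0, 0])
        coords[tail] = 1e6  # park the tail far away
        coords[tail[0]] = target
        got = nd.tail_dna_min_distance(coords, system, ("H2A.Z", 1, "C"))
        d_direct = np.linalg.norm(coords[tail[0]] - coords[window], axis=1).min()
        assert got == pytest.approx(d_direct)
        assert got <= 4.1 + 1e-9

    def test_matches_all_pairs_oracle(self, rng):
        a = rng.uniform(0, 10, size=(15, 3))
        b = rng.uniform(0, 10, size=(25, 3))
        assert min_distance(a, b) == pytest.approx(cdist(a, b).min())


class TestCorrelation:
    def test_self_and_negation(self, rng):
        y = rng.normal(size=100)
        assert nd.series_correlation(y, y) == pytest.approx(1.0)
        assert nd.series_correlation(y, -y) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nd.series_correlation(np.ones(10), np.arange(10.0))

    def test_anticoupling_strengthens_with_parameter(self):
        """Steeper bind-probability coupling gives stronger anti-correlation
        between unwrapping and C-tail contacts."""
        rs = []
        for slope in (0.05, 0.3):
            p = nd.SyntheticParams(
                n_frames=3000, seed=77, noise_sigma=0.0, epsilon=0.35,
                tail_bind_prob=lambda i, s=slope: np.clip(
                    0.9 - s * np.asarray(i, dtype=float), 0.05, 0.95))
            system, ens, truth = nd.simulate_trajectory(p)
            cs = nd.tail_dna_contact_series(ens, system, ("H2A.Z", 1, "C"),
                                            "total")
            rs.append(nd.series_correlation(truth.entry_unwrapped, cs.counts))
        assert rs[0] < 0 or rs[1] < 0
        assert rs[1] < rs[0]
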