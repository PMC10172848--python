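import numpy as np
import pytest
from scipy.stats import skew, spearmanr

from migrascape.geo import GeoPoint
from migrascape.ibd import build_sharing_matrix
from migrascape.migration import (
    MigrationSurface,
    average_replicates,
    baseline_surface,
    make_response,
    read_maps_output,
    to_dispersal,
    write_maps_output,
)


def surface_on(lattice, log10_m, demes=None, source="synthetic"):
    demes = lattice.habitable_ids if demes is None else np.asarray(demes)
    return MigrationSurface(lattice, demes, np.asarray(log10_m, dtype=float), source)


class TestReadMapsOutput:
    def write(self, tmp_path, tokens, coords):
        mrates = tmp_path / "mRates.txt"
        demes = tmp_path / "demes.txt"
        mrates.write_text(" ".join(str(t) for t in tokens) + "\n")
        demes.write_text("".join(f"{x} {y}\n" for x, y in coords))
        return mrates, demes

    def coords_of(self, lattice, ids):
        return [(lattice.lons[d], lattice.lats[d]) for d in ids]

    def test_zero_rates_give_unit_migration(self, small_lattice, tmp_path):
        ids = [0, 1, 2]
        mrates, demes = self.write(tmp_path, [0, 0, 0], self.coords_of(small_lattice, ids))
        s = read_maps_output(mrates, demes, small_lattice)
        assert np.allclose(s.m_linear, 1.0)
        assert s.deme_ids.tolist() == ids

    def test_powers_of_ten(self, small_lattice, tmp_path):
        mrates, demes = self.write(tmp_path, [-1, 0, 1], self.coords_of(small_lattice, [0, 1, 2]))
        s = read_maps_output(mrates, demes, small_lattice)
        assert np.allclose(s.m_linear, [0.1, 1.0, 10.0])

    def test_posterior_draws_averaged(self, small_lattice, tmp_path):
        # 6 tokens over 3 demes: two draws, averaged per deme on log10 scale
        mrates, demes = self.write(
            tmp_path, [0, 1, 2, 2, 3, 4], self.coords_of(small_lattice, [0, 1, 2])
        )
        s = read_maps_output(mrates, demes, small_lattice)
        assert np.allclose(s.log10_m, [1.0, 2.0, 3.0])

    def test_non_multiple_token_count_errors(self, small_lattice, tmp_path):
        mrates, demes = self.write(tmp_path, [0, 1, 2, 3], self.coords_of(small_lattice, [0, 1, 2]))
        with pytest.raises(ValueError, match="4.*3"):
            read_maps_output(mrates, demes, small_lattice)

    def test_far_away_deme_coordinate_errors(self, small_lattice, tmp_path):
        coords = self.coords_of(small_lattice, [0, 1]) + [(170.0, 80.0)]
        mrates, demes = self.write(tmp_path, [0, 0, 0], coords)
        with pytest.raises(ValueError, match="farther"):
            read_maps_output(mrates, demes, small_lattice)

    def test_write_read_round_trip_identity(self, small_lattice, tmp_path):
        rng = np.random.default_rng(3)
        s = surface_on(small_lattice, rng.normal(size=small_lattice.habitable_ids.size))
        write_maps_output(s, tmp_path / "m.txt", tmp_path / "d.txt")
        back = read_maps_output(tmp_path / "m.txt", tmp_path / "d.txt", small_lattice)
        assert np.array_equal(back.deme_ids, s.deme_ids)
        assert np.allclose(back.log10_m, s.log10_m, atol=1e-12, rtol=0)


class TestAverageReplicates:
    def test_single_surface_identity(self, small_lattice):
        s = surface_on(small_lattice, np.linspace(-1, 1, small_lattice.habitable_ids.size))
        out = average_replicates([s])
        assert np.allclose(out.log10_m, s.log10_m)

    def test_linear_scale_mean(self, small_lattice):
        n = small_lattice.habitable_ids.size
        a = surface_on(small_lattice, np.zeros(n))          # m = 1
        b = surface_on(small_lattice, np.full(n, np.log10(3.0)))  # m = 3
        out = average_replicates([a, b])
        assert np.allclose(out.m_linear, 2.0)  # arithmetic mean on linear scale

    def test_geometric_option(self, small_lattice):
        n = small_lattice.habitable_ids.size
        a = surface_on(small_lattice, np.zeros(n))
        b = surface_on(small_lattice, np.full(n, 2.0))
        out = average_replicates([a, b], geometric=True)
        assert np.allclose(out.log10_m, 1.0)

    def test_order_invariant(self, small_lattice):
        n = small_lattice.habitable_ids.size
        rng = np.random.default_rng(0)
        surfs = [surface_on(small_lattice, rng.normal(size=n)) for _ in range(3)]
        fwd = average_replicates(surfs)
        rev = average_replicates(surfs[::-1])
        assert np.allclose(fwd.log10_m, rev.log10_m)

    def test_averaging_k_copies_is_identity(self, small_lattice):
        s = surface_on(small_lattice, np.linspace(-0.5, 0.5, small_lattice.habitable_ids.size))
        out = average_replicates([s, s, s])
        assert np.allclose(out.log10_m, s.log10_m)

    def test_mismatched_support_errors(self, small_lattice):
        a = surface_on(small_lattice, [0.0, 0.0], demes=[0, 1])
        b = surface_on(small_lattice, [0.0, 0.0], demes=[0, 2])
        with pytest.raises(ValueError, match="support"):
            average_replicates([a, b])


class TestDispersal:
    def test_unit_rate(self, small_lattice):
        s = surface_on(small_lattice, np.zeros(small_lattice.habitable_ids.size))
        assert np.allclose(to_dispersal(s, 100.0).sigma_km, 100.0)

    def test_sqrt_scaling(self, small_lattice):
        s = surface_on(small_lattice, np.full(small_lattice.habitable_ids.size, np.log10(4.0)))
        assert np.allclose(to_dispersal(s, 100.0).sigma_km, 200.0)

    def test_linear_in_step(self, small_lattice):
        rng = np.random.default_rng(1)
        s = surface_on(small_lattice, rng.normal(size=small_lattice.habitable_ids.size))
        assert np.allclose(
            to_dispersal(s, 200.0).sigma_km, 2.0 * to_dispersal(s, 100.0).sigma_km
        )

    def test_nonpositive_step_errors(self, small_lattice):
        s = surface_on(small_lattice, np.zeros(small_lattice.habitable_ids.size))
        with pytest.raises(ValueError):
            to_dispersal(s, 0.0)


class TestResponse:
    def test_unit_rates_give_zero(self, small_lattice):
        s = surface_on(small_lattice, np.zeros(small_lattice.habitable_ids.size))
        assert np.allclose(make_response(s).y, 0.0)

    def test_natural_log(self, small_lattice):
        s = surface_on(
            small_lattice,
            np.full(small_lattice.habitable_ids.size, np.log10(np.e)),
        )
        assert np.allclose(make_response(s).y, 1.0)

    def test_log_reduces_skew_of_lognormal_rates(self, small_lattice):
        rng = np.random.default_rng(5)
        n = small_lattice.habitable_ids.size
        log10_m = rng.normal(0, 0.6, n)
        s = surface_on(small_lattice, log10_m)
        assert abs(skew(make_response(s).y)) < abs(skew(s.m_linear))

    def test_restricted_to_habitable(self, square_bbox):
        from migrascape.geo import build_lattice

        lattice = build_lattice(square_bbox, 12)
        lattice.habitable[::2] = False
        s = MigrationSurface(
            lattice, lattice.deme_ids, np.zeros(lattice.n_demes), "synthetic"
        )
        r = make_response(s)
        assert set(r.deme_ids) == set(lattice.habitable_ids)


class TestBaselineSurface:
    def test_constant_sharing_gives_zero_z(self, small_lattice):
        ids = ("A", "B", "C")
        counts = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        from migrascape.ibd import SharingMatrix

        m = SharingMatrix(ids, counts)
        coords = {
            "A": small_lattice.center(0),
            "B": small_lattice.center(1),
            "C": small_lattice.center(2),
        }
        s = baseline_surface(m, coords, small_lattice, bandwidth_km=500.0)
        assert np.allclose(s.log10_m, 0.0, atol=1e-9)

    def test_sharing_hotspot_raises_nearby_demes(self, small_lattice):
        # heavy sharing between two western individuals, none in the east
        from migrascape.ibd import SharingMatrix

        west = small_lattice.center(0)
        east = small_lattice.center(small_lattice.n_demes - 1)
        ids = ("w1", "w2", "e1", "e2")
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = counts[1, 0] = 10
        m = SharingMatrix(ids, counts)
        coords = {"w1": west, "w2": west, "e1": east, "e2": east}
        s = baseline_surface(m, coords, small_lattice, bandwidth_km=100.0)
        z = dict(zip(s.deme_ids.tolist(), s.log10_m))
        assert z[0] > z[small_lattice.n_demes - 1]

    def test_relabeling_invariance(self, small_lattice):
        from migrascape.ibd import SharingMatrix

        rng = np.random.default_rng(2)
        n = 6
        c = rng.integers(0, 5, (n, n))
        counts = np.triu(c, 1) + np.triu(c, 1).T
        ids = tuple(f"i{k}" for k in range(n))
        pts = {f"i{k}": small_lattice.center(k) for k in range(n)}
        s1 = baseline_surface(SharingMatrix(ids, counts), pts, small_lattice)
        perm = rng.permutation(n)
        ids2 = tuple(ids[p] for p in perm)
        counts2 = counts[np.ix_(perm, perm)]
        s2 = baseline_surface(SharingMatrix(ids2, counts2), pts, small_lattice)
        assert np.allclose(s1.log10_m, s2.log10_m)

    def test_positive_rank_correlation_with_truth_across_seeds(self):
        """Sanity floor: the heuristic surface tracks the true one in rank."""
        from migrascape.synthetic import IBDGenParams, TruthSpec, generate_dataset

        for seed in range(10):
            ds = generate_dataset(
                TruthSpec(seed=seed),
                IBDGenParams(seed=seed + 100),
                target_demes=100,
                n_individuals=120,
                with_ibd=True,
            )
            mat = build_sharing_matrix(ds.segments, ds.individual_ids)
            coords = dict(zip(ds.individual_ids, ds.individuals))
            bs = baseline_surface(mat, coords, ds.lattice)
            rho = spearmanr(bs.log10_m, ds.surface.log10_m).statistic
            assert rho > 0, f"seed {seed}: spearman {rho}"
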