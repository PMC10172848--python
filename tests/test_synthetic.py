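import numpy as np
import pytest
from scipy.stats import chisquare

from migrascape.geo import BoundingBox, GeoPoint, assign_individuals, build_lattice
from migrascape.ibd import DEFAULT_BINS
from migrascape.migration import MigrationSurface
from migrascape.synthetic import (
    DEFAULT_BBOX,
    IBDGenParams,
    TruthSpec,
    commute_distance_km,
    gen_ibd,
    gen_individuals,
    gen_rasters,
    gen_surface,
    generate_dataset,
)


class TestGenRasters:
    def test_standardized_even_unsmoothed(self):
        layers = gen_rasters(3, grid_shape=(100, 100), length_scale_px=0, seed=0)
        for layer in layers:
            assert abs(layer.values.std() - 1.0) < 0.05
            assert abs(layer.values.mean()) < 0.05

    def test_seed_reproducibility(self):
        a = gen_rasters(2, seed=42)
        b = gen_rasters(2, seed=42)
        for la, lb in zip(a, b):
            assert np.array_equal(la.values, lb.values)

    def test_layers_mutually_independent(self):
        layers = gen_rasters(10, grid_shape=(100, 100), length_scale_px=0, seed=1)
        flat = np.stack([l.values.ravel() for l in layers])
        corr = np.corrcoef(flat)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_smoothing_induces_spatial_autocorrelation(self):
        smooth = gen_rasters(1, grid_shape=(100, 100), length_scale_px=8, seed=2)[0]
        rough = gen_rasters(1, grid_shape=(100, 100), length_scale_px=0, seed=2)[0]

        def lag1(v):
            return np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]

        assert lag1(smooth.values) > 0.9 > lag1(rough.values)


@pytest.fixture(scope="module")
def lattice400():
    return build_lattice(DEFAULT_BBOX, 400)


@pytest.fixture(scope="module")
def lattice100():
    return build_lattice(DEFAULT_BBOX, 100)


@pytest.fixture(scope="module")
def flat_commute():
    lattice = build_lattice(BoundingBox(GeoPoint(0, 3), GeoPoint(3, 0)), 50)
    n = lattice.habitable_ids.size
    surface = MigrationSurface(lattice, lattice.habitable_ids, np.zeros(n), "synthetic")
    hab, R = commute_distance_km(surface, lattice)
    return lattice, surface, hab, R


class TestGenSurface:
    def test_zero_noise_fully_explainable(self, lattice400):
        truth = TruthSpec(n_layers=3, causal_ids=(0,), betas=(1.0,), links=("linear",),
                          noise_sd=0.0, target_explainable_variance=None, seed=0)
        layers = gen_rasters(3, seed=0)
        _, ev = gen_surface(layers, lattice400, truth)
        assert ev == pytest.approx(1.0)

    def test_pure_noise_explains_nothing(self, lattice400):
        truth = TruthSpec(n_layers=2, causal_ids=(), betas=(), links=(),
                          noise_sd=1.0, target_explainable_variance=None, seed=0)
        layers = gen_rasters(2, seed=0)
        _, ev = gen_surface(layers, lattice400, truth)
        assert ev == 0.0

    def test_equal_signal_noise_gives_half(self, lattice400):
        # one linear unit effect on a standardized layer with matched noise
        layers = gen_rasters(1, seed=3)
        truth = TruthSpec(n_layers=1, causal_ids=(0,), betas=(1.0,), links=("linear",),
                          noise_sd=1.0, target_explainable_variance=None, seed=3)
        _, ev = gen_surface(layers, lattice400, truth)
        assert ev == pytest.approx(0.5, abs=0.05)

    def test_target_explainable_variance_honored(self, lattice400):
        truth = TruthSpec(seed=11)  # defaults target 0.45 with 3 mixed links
        layers = gen_rasters(truth.n_layers, seed=11)
        _, ev = gen_surface(layers, lattice400, truth)
        assert 0.40 <= ev <= 0.50

    def test_missing_causal_layer_errors(self, lattice400):
        truth = TruthSpec(n_layers=5, causal_ids=(4,), betas=(1.0,), links=("linear",),
                          noise_sd=0.1, target_explainable_variance=None)
        with pytest.raises(ValueError, match="missing|index"):
            gen_surface(gen_rasters(3, seed=0), lattice400, truth)


class TestGenIndividuals:
    def test_unclustered_sampling_is_uniform_over_demes(self, lattice100):
        pts = gen_individuals(lattice100, 2000, clustering=0.0, seed=0)
        demes = assign_individuals(lattice100, pts)
        counts = np.bincount(demes, minlength=lattice100.n_demes)[lattice100.habitable_ids]
        stat = chisquare(counts)
        assert stat.pvalue > 0.01

    def test_fully_clustered_mass_near_centers(self, lattice100):
        pts = gen_individuals(lattice100, 500, clustering=1.0, seed=1)
        # recover the cluster centers the generator picked
        rng = np.random.default_rng(1)
        hab = lattice100.habitable_ids
        centers = hab[rng.choice(hab.size, size=5, replace=False)]
        from migrascape.geo import pairwise_great_circle_km

        d = pairwise_great_circle_km(
            np.array([p.lon for p in pts])[:, None],
            np.array([p.lat for p in pts])[:, None],
            lattice100.lons[centers][None, :],
            lattice100.lats[centers][None, :],
        ).min(axis=1)
        sd_km = 2.0 * lattice100.step_km
        # 2-D Gaussian: >98% of mass within 3 sd of its own center
        assert (d <= 3 * np.hypot(sd_km, sd_km)).mean() >= 0.90

    def test_seed_reproducibility(self, lattice100):
        a = gen_individuals(lattice100, 50, seed=7)
        b = gen_individuals(lattice100, 50, seed=7)
        assert [(p.lon, p.lat) for p in a] == [(p.lon, p.lat) for p in b]

    def test_points_stay_in_bbox(self, lattice100):
        for p in gen_individuals(lattice100, 300, clustering=1.0, seed=2):
            assert lattice100.bbox.contains(p)


class TestCommuteDistance:
    def test_metric_properties_on_sampled_triples(self, flat_commute):
        _, _, _, R = flat_commute
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 0.0)
        assert np.all(R[~np.eye(len(R), dtype=bool)] > 0)
        rng = np.random.default_rng(0)
        n = len(R)
        for _ in range(200):
            i, j, k = rng.integers(0, n, 3)
            assert R[i, j] <= R[i, k] + R[k, j] + 1e-9

    def test_nearest_neighbor_scale_matches_step(self, flat_commute):
        lattice, _, _, R = flat_commute
        pos = {int(d): i for i, d in enumerate(lattice.habitable_ids)}
        nn = [R[pos[i], pos[j]] for i, j in lattice.edges()]
        assert np.mean(nn) == pytest.approx(lattice.step_km, rel=1e-6)

    def test_corridor_raises_connectivity(self):
        """Raising migration along a corridor lowers resistance across it."""
        lattice = build_lattice(BoundingBox(GeoPoint(0, 3), GeoPoint(6, 0)), 60)
        n = lattice.n_demes
        flat = MigrationSurface(lattice, lattice.deme_ids, np.zeros(n), "synthetic")
        log10_m = np.zeros(n)
        mid_row = lattice.n_rows // 2
        corridor = [d for d in range(n) if d // lattice.n_cols == mid_row]
        log10_m[corridor] = 1.0  # 10x migration along the corridor row
        boosted = MigrationSurface(lattice, lattice.deme_ids, log10_m, "synthetic")
        _, R0 = commute_distance_km(flat, lattice)
        _, R1 = commute_distance_km(boosted, lattice)
        west, east = corridor[0], corridor[-1]
        # compare rescaled distances relative to each surface's own step scale
        assert R1[west, east] / R1.max() < R0[west, east] / R0.max()

    def test_disconnected_graph_errors(self):
        lattice = build_lattice(BoundingBox(GeoPoint(0, 3), GeoPoint(3, 0)), 30)
        # split habitability into two unconnected halves by removing a row band
        band = [d for d in range(lattice.n_demes)
                if d // lattice.n_cols == lattice.n_rows // 2]
        lattice.habitable[band] = False
        n = lattice.habitable_ids.size
        s = MigrationSurface(lattice, lattice.habitable_ids, np.zeros(n), "synthetic")
        with pytest.raises(ValueError, match="disconnected"):
            commute_distance_km(s, lattice)


class TestGenIBD:
    def test_same_deme_pairs_poisson_mean(self):
        """Colocated pairs: observed mean sharing within 3 SE of the base rate."""
        lattice = build_lattice(BoundingBox(GeoPoint(0, 2), GeoPoint(2, 0)), 20)
        n = lattice.habitable_ids.size
        surface = MigrationSurface(lattice, lattice.habitable_ids, np.zeros(n), "synthetic")
        # 46 individuals in one deme -> 1035 colocated pairs (rho = 0)
        demes = np.full(46, int(lattice.habitable_ids[0]))
        params = IBDGenParams(seed=5)
        segs = gen_ibd(surface, lattice, demes, params, DEFAULT_BINS)
        from migrascape.ibd import bin_segments

        n_pairs = 46 * 45 // 2
        for b, bucket in zip(range(3), bin_segments(segs, DEFAULT_BINS)):
            c = params.rate_for(b)
            observed = len(bucket) / n_pairs
            se = np.sqrt(c / n_pairs)
            assert abs(observed - c) <= 3 * se, f"bin {b}: {observed} vs {c}"

    def test_sharing_decays_with_distance(self):
        ds = generate_dataset(
            TruthSpec(seed=0), IBDGenParams(seed=1), target_demes=60,
            n_individuals=80, clustering=0.0,
        )
        from migrascape.ibd import build_sharing_matrix
        from migrascape.geo import pairwise_great_circle_km

        mat = build_sharing_matrix(ds.segments, ds.individual_ids)
        iu, ju = np.triu_indices(len(ds.individuals), k=1)
        lon = np.array([p.lon for p in ds.individuals])
        lat = np.array([p.lat for p in ds.individuals])
        d = pairwise_great_circle_km(lon[iu], lat[iu], lon[ju], lat[ju])
        c = mat.counts[iu, ju]
        near = c[d < np.median(d)].mean()
        far = c[d >= np.median(d)].mean()
        assert near > far

    def test_segments_respect_bin_ranges_and_toy_map(self):
        ds = generate_dataset(
            TruthSpec(seed=2), IBDGenParams(seed=3), target_demes=50, n_individuals=40,
        )
        assert ds.segments, "expected some segments"
        for s in ds.segments:
            assert s.length_cM >= 2.0
            assert s.start_bp < s.end_bp
            assert (s.end_bp - s.start_bp) == pytest.approx(s.length_cM * 1e6, rel=0.01)

    def test_seed_reproducibility(self):
        a = generate_dataset(TruthSpec(seed=4), IBDGenParams(seed=5),
                             target_demes=50, n_individuals=30)
        b = generate_dataset(TruthSpec(seed=4), IBDGenParams(seed=5),
                             target_demes=50, n_individuals=30)
        assert a.segments == b.segments
        assert np.array_equal(a.surface.log10_m, b.surface.log10_m)
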