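import numpy as np
import pytest

from nanomap import alignment, digest as digest_mod, simulate
from nanomap.alignment import (
    align_maps,
    batch_align,
    brute_force_align,
    estimate_bpp,
    estimate_fp_rate,
    mapping_length_ratio,
)
from nanomap.models import AlignParams, DigestParams, LabelMap, NoiseModel, ValidationError


@pytest.fixture(scope="module")
def ref_map(small_digest_module):
    return small_digest_module.maps.maps[0]


@pytest.fixture(scope="module")
def small_digest_module():
    g = simulate.simulate_genome(500_000, seed=101)
    return digest_mod.digest_sequences([g], DigestParams())


class TestAlignMaps:
    def test_self_alignment_full_ratio_forward(self, ref_map):
        aln = align_maps(ref_map, ref_map)
        assert aln.orientation == "+"
        assert aln.mapping_length_ratio == pytest.approx(1.0)
        assert aln.thorough
        assert aln.n_pairs == ref_map.n_labels

    def test_mirror_image_aligns_reverse(self, ref_map):
        mirror = LabelMap("mir", ref_map.length,
                          np.sort(ref_map.length - ref_map.labels))
        aln = align_maps(mirror, ref_map)
        assert aln.orientation == "-"
        assert aln.mapping_length_ratio == pytest.approx(1.0)

    def test_reversal_symmetry_of_score(self, ref_map):
        mirror = LabelMap("mir", ref_map.length,
                          np.sort(ref_map.length - ref_map.labels))
        a1 = align_maps(ref_map, ref_map)
        a2 = align_maps(mirror, ref_map)
        assert a1.score == pytest.approx(a2.score, rel=1e-9)

    def test_min_sites_filter(self, ref_map):
        few = LabelMap("few", 100_000.0, np.linspace(1000, 90_000, 5))
        assert align_maps(few, ref_map) is None  # fewer than 7 labels

    def test_thorough_classification_matches_threshold(self, ref_map):
        aln = align_maps(ref_map, ref_map)
        assert aln.thorough == (aln.mapping_length_ratio >= alignment.THOROUGH_RATIO)
        assert alignment.THOROUGH_RATIO == 0.95


class TestBruteForceOracle:
    def test_empty_pairing_baseline(self):
        q = LabelMap("q", 10_000.0, np.array([100.0]))
        r = LabelMap("r", 10_000.0, np.array([9000.0]))
        params = AlignParams(min_score=1e9)
        score, _ori, _pairs = brute_force_align(q, r, params)
        assert score >= 0.0

    def test_equal_spacing_identity_pairing(self):
        q = LabelMap("q", 40_000.0, np.array([10_000.0, 20_000.0, 30_000.0]))
        score, ori, pairs = brute_force_align(q, q, AlignParams())
        assert ori == "+"
        assert pairs == [(0, 0), (1, 1), (2, 2)]
        assert score == pytest.approx(3 * AlignParams().bonus)

    def test_size_bound_enforced(self):
        big = LabelMap("b", 100_000.0, np.linspace(1000, 99_000, 9))
        with pytest.raises(ValidationError):
            brute_force_align(big, big)

    @pytest.mark.parametrize("seed", range(4))
    def test_dp_equals_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        params = AlignParams()
        for _ in range(60):
            nq, nr = rng.integers(2, 7, size=2)
            L = 60_000.0
            q = LabelMap("q", L, np.sort(rng.uniform(0, L, nq)))
            r = LabelMap("r", L, np.sort(rng.uniform(0, L, nr)))
            oracle_score, _, _ = brute_force_align(q, r, params)
            dp_score, _ori, qk, _rj = alignment.align_label_arrays(
                q.labels, q.length, r.labels, params)
            assert max(dp_score, 0.0) == pytest.approx(oracle_score, abs=1e-6)


class TestMappingLengthRatio:
    def test_full_span_is_one(self, ref_map):
        aln = align_maps(ref_map, ref_map)
        assert mapping_length_ratio(aln) == pytest.approx(1.0)

    def test_half_span(self, ref_map):
        # first half of the query matches the reference; the second half
        # carries an unrelated label pattern, so the ratio is about 0.5
        rng = np.random.default_rng(99)
        L = ref_map.length
        far = np.sort(rng.uniform(L + 20_000, 2 * L - 5_000, 25))
        half = LabelMap("h", 2 * L, np.concatenate([ref_map.labels, far]))
        aln = align_maps(half, ref_map)
        assert aln is not None
        assert 0.35 <= aln.mapping_length_ratio <= 0.65

    def test_rescaled_denominator(self, ref_map):
        aln = align_maps(ref_map, ref_map)
        assert mapping_length_ratio(aln, ref_map.length * 2) == pytest.approx(0.5, abs=0.02)


class TestBatchAlign:
    def test_identity_all_thorough(self, small_digest_module):
        maps = small_digest_module.maps
        result = batch_align(maps, maps)
        assert result.frac_ratio_ge[0.95] == 1.0

    def test_site_filter_count(self, ref_map):
        rng = np.random.default_rng(0)
        queries = []
        for i in range(10):
            n = 5 if i < 3 else 9
            queries.append(LabelMap(f"q{i}", 120_000.0,
                                    np.sort(rng.uniform(0, 120_000.0, n))))
        result = batch_align(queries, [ref_map])
        assert result.n_retained == 7


class TestEstimators:
    @pytest.fixture(scope="class")
    def genome_and_ref(self):
        g = simulate.simulate_genome(1_000_000, seed=22)
        ref = digest_mod.digest_sequences([g], DigestParams()).maps.maps[0]
        return g, ref

    def _align_molecules(self, dataset, ref):
        alns = []
        for m in dataset.molecules:
            a = align_maps(m.as_label_map(), ref, AlignParams(), compute_confidence=False)
            if a is not None:
                alns.append(a)
        return alns

    def test_noise_free_fp_rate_zero(self, genome_and_ref):
        g, ref = genome_and_ref
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=10,
                                          noise=NoiseModel.noise_free(), seed=1)
        alns = self._align_molecules(ds, ref)
        assert len(alns) > 10
        assert estimate_fp_rate(alns) == 0.0

    def test_bpp_identity_scale_with_quantization(self, genome_and_ref):
        g, ref = genome_and_ref
        noise = NoiseModel(fp_rate=0, fn_prob=0, sizing_sd_scale=0,
                           stretch_mean=1.0, stretch_sd=0, bpp=500)
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=10, noise=noise, seed=2)
        alns = self._align_molecules(ds, ref)
        assert estimate_bpp(alns) == pytest.approx(500.0, abs=1.0)

    def test_bpp_tracks_planted_shrink(self, genome_and_ref):
        g, ref = genome_and_ref
        noise = NoiseModel(stretch_mean=0.99, stretch_sd=0.005)
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=30, noise=noise, seed=3)
        alns = self._align_molecules(ds, ref)
        assert estimate_bpp(alns) == pytest.approx(495.0, abs=2.5)

    def test_fp_rate_tracks_doubled_rate(self, genome_and_ref):
        g, ref = genome_and_ref
        noise = NoiseModel(fp_rate=3.0)
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=40, noise=noise, seed=4)
        alns = self._align_molecules(ds, ref)
        est = estimate_fp_rate(alns)
        assert 2.2 <= est <= 3.4
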