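import numpy as np
import pytest
from scipy import stats as sps

from nanomap import digest as digest_mod
from nanomap import formats, simulate
from nanomap.models import (
    DigestParams,
    MoleculeLengthModel,
    NoiseModel,
    ValidationError,
)
from nanomap.stats import n50


class TestSimulateGenome:
    def test_same_seed_identical(self):
        a = simulate.simulate_genome(50_000, seed=3)
        b = simulate.simulate_genome(50_000, seed=3)
        assert a.sequence == b.sequence

    def test_distinct_seeds_differ(self):
        assert (simulate.simulate_genome(50_000, seed=3).sequence
                != simulate.simulate_genome(50_000, seed=4).sequence)

    def test_realized_density_near_target(self):
        g = simulate.simulate_genome(1_000_000, target_label_density=11.0, seed=5)
        result = digest_mod.digest_sequences([g], DigestParams())
        n_labels = result.maps.maps[0].n_labels
        lo, hi = sps.poisson.interval(0.99, 110)
        assert lo <= n_labels <= hi

    def test_target_zero_leaves_background_expectation(self):
        # at 50% GC the double-strand background for a 7-mer is 2 * (L-6) / 4^7
        L = 2_000_000
        with pytest.warns(UserWarning):
            g = simulate.simulate_genome(L, gc=0.5, target_label_density=0.0, seed=6)
        sites = digest_mod.find_motif_sites(g, "GCTCTTC")
        expected = 2 * (L - 6) * 0.25 ** 7
        lo, hi = sps.poisson.interval(0.999, expected)
        assert lo <= len(sites) <= hi

    def test_nick_density_target_plants_close_pairs(self):
        g = simulate.simulate_genome(2_000_000, target_label_density=11.0,
                                     target_nick_density=13.7, seed=7)
        result = digest_mod.digest_sequences([g], DigestParams())
        assert result.nick_density == pytest.approx(13.7, abs=2.0)
        assert result.label_density == pytest.approx(11.0, abs=1.5)
        assert result.label_density < result.nick_density


class TestLengthModel:
    def test_stopping_rule_and_truncation(self):
        model = MoleculeLengthModel()
        intervals = simulate.sample_molecule_intervals(1_000_000, 10, model, seed=1)
        total = sum(e - s for s, e in intervals)
        assert 10e6 <= total <= 10e6 + 1_000_000
        assert min(e - s for s, e in intervals) >= model.min_len

    def test_n50_calibration(self):
        model = MoleculeLengthModel()
        intervals = simulate.sample_molecule_intervals(50_000_000, 10, model, seed=2)
        lengths = [e - s for s, e in intervals]
        assert len(lengths) >= 2000
        assert n50(lengths) == pytest.approx(model.target_n50, rel=0.10)

    def test_genome_shorter_than_min_len_rejected(self):
        with pytest.raises(ValidationError):
            simulate.sample_molecule_intervals(50_000, 5, MoleculeLengthModel(), seed=0)


class TestCorruptMolecule:
    def test_zero_noise_identity(self):
        true = np.array([1000.0, 5000.0, 20_000.0])
        mol = simulate.corrupt_molecule(true, 120_000.0, NoiseModel.noise_free(), seed=0)
        np.testing.assert_allclose(mol.labels, true)
        assert mol.length == 120_000.0
        assert mol.truth["n_dropped"] == 0

    def test_all_fn_no_fp_gives_no_labels(self):
        noise = NoiseModel(fn_prob=1.0, fp_rate=0.0, sizing_sd_scale=0,
                           stretch_mean=1.0, stretch_sd=0, bpp=0)
        mol = simulate.corrupt_molecule(np.arange(10) * 10_000.0 + 500, 120_000.0,
                                        noise, seed=1)
        assert mol.n_labels == 0
        assert mol.truth["n_dropped"] == 10

    def test_fn_fraction_within_binomial_interval(self):
        noise = NoiseModel(fn_prob=0.15, fp_rate=0.0, sizing_sd_scale=0,
                           stretch_mean=1.0, stretch_sd=0, bpp=0)
        n_total = 0
        n_drop = 0
        for i in range(200):
            true = np.arange(60) * 2000.0 + 700
            mol = simulate.corrupt_molecule(true, 130_000.0, noise, seed=i)
            n_total += mol.truth["n_true"]
            n_drop += mol.truth["n_dropped"]
        assert n_total >= 10_000
        lo, hi = sps.binom.interval(0.99, n_total, 0.15)
        assert lo <= n_drop <= hi

    def test_observed_gaps_respect_resolution(self):
        mol = simulate.corrupt_molecule(np.arange(30) * 4000.0 + 600, 130_000.0,
                                        NoiseModel(), seed=9)
        if mol.n_labels > 1:
            assert np.diff(mol.labels).min() >= NoiseModel().resolution_bp


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def genome(self):
        return simulate.simulate_genome(600_000, seed=55)

    def test_zero_noise_molecules_match_restricted_digest(self, genome):
        ds, truth = simulate.generate_dataset(
            genome, DigestParams(), depth=5, noise=NoiseModel.noise_free(), seed=2)
        gmap, _ = digest_mod.digest_record(genome, DigestParams())
        sites = gmap.labels
        for mol, row in zip(ds.molecules, truth.itertuples()):
            seg = sites[(sites >= row.start) & (sites <= row.end)]
            expected = seg - row.start if row.strand == "+" else (row.end - seg)[::-1]
            np.testing.assert_allclose(mol.labels, expected)

    def test_same_seed_byte_identical_bnx(self, genome, tmp_path):
        for name in ("a.bnx", "b.bnx"):
            ds, _ = simulate.generate_dataset(genome, DigestParams(), depth=3, seed=4)
            formats.write_bnx(ds, tmp_path / name)
        assert (tmp_path / "a.bnx").read_bytes() == (tmp_path / "b.bnx").read_bytes()

    def test_distinct_seeds_differ(self, genome):
        d1, _ = simulate.generate_dataset(genome, DigestParams(), depth=3, seed=4)
        d2, _ = simulate.generate_dataset(genome, DigestParams(), depth=3, seed=5)
        assert [m.length for m in d1.molecules] != [m.length for m in d2.molecules]

    def test_mean_density_close_to_fp_plus_retained_truth(self, genome):
        ds, _ = simulate.generate_dataset(genome, DigestParams(), depth=40, seed=6)
        gmap, _ = digest_mod.digest_record(genome, DigestParams())
        true_density = gmap.n_labels / genome.length * 1e5
        noise = NoiseModel()
        expected = noise.fp_rate + (1 - noise.fn_prob) * true_density
        total_labels = sum(m.n_labels for m in ds.molecules)
        total_len = ds.total_length()
        observed = total_labels / total_len * 1e5
        assert observed == pytest.approx(expected, rel=0.15)


class TestValidateRates:
    def test_zero_noise_rates_are_zero(self):
        g = simulate.simulate_genome(400_000, seed=12)
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=5,
                                          noise=NoiseModel.noise_free(), seed=3)
        fp, fn = simulate.validate_rates(ds)
        assert fp == 0.0 and fn == 0.0

    def test_half_fn_recovered(self):
        g = simulate.simulate_genome(400_000, seed=13)
        noise = NoiseModel(fn_prob=0.5)
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=30, noise=noise, seed=4)
        _fp, fn = simulate.validate_rates(ds)
        n_true = sum(m.truth["n_true"] for m in ds.molecules)
        lo, hi = sps.binom.interval(0.999, n_true, 0.5)
        assert lo / n_true <= fn <= hi / n_true

    def test_missing_truth_rejected(self):
        from nanomap.models import BnxDataset, Molecule
        ds = BnxDataset(molecules=[Molecule("m", 1e5, np.array([1000.0]))])
        with pytest.raises(ValidationError):
            simulate.validate_rates(ds)
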