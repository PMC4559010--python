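import numpy as np
import pytest

from nanomap import alignment, assembly, digest as digest_mod, formats, simulate
from nanomap.assembly import (
    Placement,
    anchor_cluster,
    assemble,
    call_consensus,
    cluster_molecules,
    depth_titration,
    mol_distance,
    pairwise_distances,
)
from nanomap.models import (
    AssemblyParams,
    BnxDataset,
    DigestParams,
    Molecule,
    MoleculeLengthModel,
    NoiseModel,
    ValidationError,
)


def _molecule_from_digest(sites, start, end, mol_id, reverse=False):
    seg = sites[(sites >= start) & (sites <= end)]
    labels = seg - start if not reverse else np.sort(end - seg)
    return Molecule(mol_id, float(end - start), labels)


@pytest.fixture(scope="module")
def genome_sites():
    g = simulate.simulate_genome(1_000_000, seed=31)
    gmap, _ = digest_mod.digest_record(g, DigestParams())
    return g, gmap.labels


class TestMolDistance:
    def test_identical_patterns_distance_zero(self, genome_sites):
        _, sites = genome_sites
        a = _molecule_from_digest(sites, 100_000, 280_000, "a")
        b = _molecule_from_digest(sites, 100_000, 280_000, "b")
        assert mol_distance(a, b) == pytest.approx(0.0, abs=0.05)

    def test_disjoint_regions_far_beyond_cluster_cut(self, genome_sites):
        # chance local matches keep the distance below 1, but molecules from
        # non-overlapping regions must stay far above the clustering cut
        _, sites = genome_sites
        a = _molecule_from_digest(sites, 50_000, 250_000, "a")
        b = _molecule_from_digest(sites, 600_000, 800_000, "b")
        d = mol_distance(a, b)
        assert d >= 0.75
        assert d > AssemblyParams().cluster_cut + 0.2

    def test_symmetry(self, genome_sites):
        _, sites = genome_sites
        rng = np.random.default_rng(1)
        for _ in range(5):
            s1, s2 = rng.integers(0, 700_000, size=2)
            a = _molecule_from_digest(sites, s1, s1 + 200_000, "a")
            b = _molecule_from_digest(sites, s2, s2 + 200_000, "b")
            assert mol_distance(a, b) == pytest.approx(mol_distance(b, a), abs=1e-9)

    def test_too_few_labels_maximal(self):
        a = Molecule("a", 150_000.0, np.array([70_000.0]))
        b = Molecule("b", 150_000.0, np.array([10_000.0, 90_000.0]))
        assert mol_distance(a, b) == 1.0


class TestClusterMolecules:
    def test_two_separated_regions_two_pure_clusters(self, genome_sites):
        _, sites = genome_sites
        rng = np.random.default_rng(2)
        mols, origin = [], []
        for k, base in enumerate((0, 700_000)):
            for i in range(12):
                start = base + rng.integers(0, 100_000)
                mols.append(_molecule_from_digest(sites, start, start + 180_000,
                                                  f"m{k}_{i}"))
                origin.append(k)
        condensed, _ = pairwise_distances(mols, AssemblyParams())
        clusters, discarded = cluster_molecules(condensed, AssemblyParams())
        assert len(clusters) == 2
        for members in clusters:
            assert len({origin[i] for i in members}) == 1

    def test_identical_molecules_single_cluster(self, genome_sites):
        _, sites = genome_sites
        mols = [_molecule_from_digest(sites, 100_000, 300_000, f"m{i}")
                for i in range(6)]
        condensed, _ = pairwise_distances(mols, AssemblyParams())
        clusters, _ = cluster_molecules(condensed, AssemblyParams())
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_cut_zero_singletons_all_discarded(self, genome_sites):
        # shifts large enough that every pattern differs -> positive distances
        _, sites = genome_sites
        mols = [_molecule_from_digest(sites, 100_000 + 40_000 * i, 300_000 + 40_000 * i,
                                      f"m{i}") for i in range(5)]
        params = AssemblyParams(cluster_cut=0.0)
        condensed, _ = pairwise_distances(mols, params)
        assert condensed.min() > 0
        clusters, discarded = cluster_molecules(condensed, params)
        assert clusters == []
        assert len(discarded) == 5


class TestAnchorCluster:
    def test_noise_free_offsets_recover_start_differences(self, genome_sites):
        _, sites = genome_sites
        starts = [100_000, 130_000, 160_000, 190_000]
        mols = [_molecule_from_digest(sites, s, s + 200_000, f"m{i}")
                for i, s in enumerate(starts)]
        placements, aside = anchor_cluster(mols, AssemblyParams())
        assert aside == []
        offsets = {p.index: p.offset for p in placements}
        base = offsets[0] - 0  # seed may be any molecule; compare differences
        for i, s in enumerate(starts):
            assert offsets[i] - offsets[0] == pytest.approx(s - starts[0], abs=200)
            assert placements[i].orientation == "+" or placements[i].scale > 0

    def test_reversed_copy_placed_reverse(self, genome_sites):
        _, sites = genome_sites
        fwd = [_molecule_from_digest(sites, 100_000 + 20_000 * i, 320_000 + 20_000 * i,
                                     f"f{i}") for i in range(3)]
        rev = _molecule_from_digest(sites, 140_000, 360_000, "r0", reverse=True)
        placements, aside = anchor_cluster(fwd + [rev], AssemblyParams())
        by_idx = {p.index: p for p in placements}
        assert 3 in by_idx
        assert by_idx[3].scale < 0

    def test_single_molecule_trivial(self):
        mol = Molecule("m", 150_000.0, np.linspace(1000, 140_000, 12))
        placements, aside = anchor_cluster([mol], AssemblyParams())
        assert len(placements) == 1 and aside == []


class TestCallConsensus:
    def test_single_molecule_consensus_equals_labels(self):
        mol = Molecule("m", 150_000.0, np.linspace(1000, 140_000, 12))
        cmap = call_consensus([mol], [Placement(0, 1.0, 0.0)], AssemblyParams())
        assert cmap.n_labels == 12
        np.testing.assert_allclose(np.sort(cmap.labels + 0.0), cmap.labels)

    def test_exact_copies_recover_true_labels(self, genome_sites):
        _, sites = genome_sites
        mols = [_molecule_from_digest(sites, 100_000, 300_000, f"m{i}")
                for i in range(10)]
        placements = [Placement(i, 1.0, 0.0) for i in range(10)]
        cmap = call_consensus(mols, placements, AssemblyParams())
        expected = mols[0].labels
        assert cmap.n_labels == len(expected)
        np.testing.assert_allclose(cmap.labels, expected, atol=60)
        assert all(s == 10 for s in cmap.support)

    def test_consensus_gaps_respect_resolution(self, genome_sites):
        _, sites = genome_sites
        mols = [_molecule_from_digest(sites, 100_000, 300_000, f"m{i}")
                for i in range(5)]
        cmap = call_consensus(mols, [Placement(i, 1.0, 0.0) for i in range(5)],
                              AssemblyParams())
        if cmap.n_labels > 1:
            assert np.diff(cmap.labels).min() >= AssemblyParams().resolution_bp


class TestAssemble:
    def test_empty_dataset(self):
        maps, report = assemble(BnxDataset())
        assert len(maps) == 0

    def test_zero_noise_round_trip_small(self, genome_sites):
        g, sites = genome_sites
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=30,
                                          noise=NoiseModel.noise_free(), seed=8)
        maps, report = assemble(ds)
        assert maps.total_length() == pytest.approx(g.length, rel=0.05)
        digest_maps = digest_mod.digest_sequences([g], DigestParams()).maps
        batch = alignment.batch_align(maps, digest_maps)
        assert batch.n_aligned == len(maps)
        assert all(a.thorough for a in batch.alignments.values())

    def test_deterministic_cmap_bytes(self, genome_sites, tmp_path):
        g, _ = genome_sites
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=15,
                                          noise=NoiseModel.noise_free(), seed=9)
        for name in ("a.cmap", "b.cmap"):
            maps, _r = assemble(ds)
            formats.write_cmap(maps, tmp_path / name)
        assert (tmp_path / "a.cmap").read_bytes() == (tmp_path / "b.cmap").read_bytes()


class TestDepthTitration:
    def test_depth_exceeding_dataset_rejected(self, genome_sites):
        g, _ = genome_sites
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=5,
                                          noise=NoiseModel.noise_free(), seed=10)
        with pytest.raises(ValidationError):
            depth_titration(ds, g.length, [50], seed=0)

    def test_full_depth_equals_direct_assembly(self, genome_sites):
        g, _ = genome_sites
        ds, _ = simulate.generate_dataset(g, DigestParams(), depth=8,
                                          noise=NoiseModel.noise_free(), seed=11)
        full_depth = ds.total_length() / g.length
        result = depth_titration(ds, g.length, [full_depth], seed=1)
        maps, _ = assemble(ds)
        assert result.map_counts[0] == len(maps)
        lengths = maps.lengths()
        from nanomap.stats import n50
        assert result.n50s[0] == pytest.approx(n50(lengths))
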