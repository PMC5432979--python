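"""Population generator: frequency spectrum, LD structure, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import chisquare

from gwasprec.popgen import (
    GenotypeMatrix,
    HaplotypePanel,
    filter_variants,
    founder_weights,
    generate_founders,
    generate_population,
    haplotypes_to_genotypes,
    ld_r2,
    mosaic_paths,
    sample_sfs,
    variant_table,
)


class TestFounders:
    def test_minimal_panel_size_contract(self):
        panel = generate_founders(2, 1, 1000, seed=0)
        assert panel.positions.shape == (1,)
        assert panel.alleles.shape == (4, 1)
        assert 1 <= panel.positions[0] <= 1000

    def test_same_seed_bitwise_identical(self):
        a = generate_founders(20, 100, 50_000, seed=42)
        b = generate_founders(20, 100, 50_000, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.alleles, b.alleles)

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError, match="distinct positions"):
            generate_founders(5, 101, 100, seed=0)

    def test_sfs_matches_truncated_neutral_density(self, rng):
        """Inverse-CDF draws follow the 1/p density on log-spaced bins,
        against a numerical-integration oracle."""
        p_min, p_max = 1e-3, 0.5
        draws = sample_sfs(50_000, 1.0, p_min, p_max, rng)
        assert draws.min() >= p_min and draws.max() <= p_max
        edges = np.geomspace(p_min, p_max, 12)
        norm = integrate.quad(lambda p: 1.0 / p, p_min, p_max)[0]
        expected = np.array(
            [
                integrate.quad(lambda p: 1.0 / p / norm, lo, hi)[0]
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        observed = np.histogram(draws, bins=edges)[0]
        stat, pval = chisquare(observed, expected * draws.size)
        assert pval > 1e-3

    def test_positions_strictly_increasing_in_bounds(self):
        panel = generate_founders(10, 500, 10_000, seed=3)
        assert np.all(np.diff(panel.positions) > 0)
        assert panel.positions[0] >= 1 and panel.positions[-1] <= 10_000


class TestMosaic:
    def test_zero_switch_zero_mutation_copies_a_founder(self):
        founders = generate_founders(10, 60, 100_000, seed=1)
        pop = generate_population(founders, 25, 0.0, 0.0, seed=2)
        founder_rows = {f.tobytes() for f in founders.alleles}
        for hap in pop.alleles:
            assert hap.tobytes() in founder_rows

    def test_switch_count_matches_closed_form(self):
        """Observable template changes per haplotype match
        sum(ps) * (1 - 1/F) under uniform copying, within binomial error."""
        founders = generate_founders(25, 300, 2_000_000, seed=5)
        n_hap, F = 600, founders.haplotype_count
        paths = mosaic_paths(founders, n_hap, 3e-6, seed=9)
        ps = 1.0 - np.exp(-3e-6 * np.diff(founders.positions))
        expected_per_hap = ps.sum() * (1.0 - 1.0 / F)
        observed = (paths[:, 1:] != paths[:, :-1]).sum()
        total_expected = n_hap * expected_per_hap
        sd = np.sqrt(n_hap * ps.size * 0.25)  # crude binomial bound
        assert abs(observed - total_expected) < 4 * sd

    def test_mutation_free_alleles_come_from_founders(self):
        founders = generate_founders(8, 40, 50_000, seed=1)
        pop = generate_population(founders, 30, 1e-4, 0.0, seed=2)
        col_sets = [set(founders.alleles[:, s]) for s in range(founders.n_sites)]
        for s in range(pop.n_sites):
            assert set(pop.alleles[:, s]) <= col_sets[s]

    def test_empty_founders_rejected(self):
        founders = generate_founders(4, 10, 1000, seed=0)
        empty = HaplotypePanel(
            founders.positions[:0], founders.alleles[:, :0], founders.region_length
        )
        with pytest.raises(ValueError):
            mosaic_paths(empty, 10, 1e-6, seed=0)

    def test_founder_weights_normalized_and_skewed(self):
        w = founder_weights(100, 1.3)
        assert w.shape == (100,)
        assert np.isclose(w.sum(), 1.0)
        assert w[0] > w[-1]
        assert np.allclose(founder_weights(10, 0.0), 0.1)

    def test_ld_r2_decays_with_distance(self):
        """Mean r^2, binned by pair distance, is non-increasing from the
        nearest to the farthest bin over 30 independent populations."""
        edges = np.array([0, 10_000, 50_000, 200_000, 1_000_000, 2_000_000])
        sums = np.zeros(5)
        counts = np.zeros(5)
        for rep in range(30):
            founders = generate_founders(
                30, 400, 2_000_000, seed=1000 + rep, ld_length=30_000.0
            )
            pop = generate_population(founders, 150, 2e-6, 1e-3, seed=2000 + rep)
            geno = haplotypes_to_genotypes(pop)
            X = geno.dosages.astype(float)
            sd = X.std(axis=0)
            ok = np.flatnonzero(sd > 0)
            Xz = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
            pos = geno.positions[ok]
            rng = np.random.default_rng(3000 + rep)
            for _ in range(3000):
                i, j = rng.integers(ok.size, size=2)
                d = abs(pos[i] - pos[j])
                if d == 0:
                    continue
                b = np.searchsorted(edges, d) - 1
                if 0 <= b < 5:
                    r = float(Xz[:, i] @ Xz[:, j]) / Xz.shape[0]
                    sums[b] += r * r
                    counts[b] += 1
        mean_r2 = sums / counts
        assert mean_r2[0] > mean_r2[-1]
        # monotone non-increasing within Monte-Carlo tolerance
        assert np.all(np.diff(mean_r2) < 0.01)

    def test_rare_variants_have_fewer_high_ld_proxies(self, contrast_cohort):
        """Mean count of r^2 > 0.8 partners within 100 Kbp is lower for rare
        than for common focal variants."""
        X = contrast_cohort.geno.dosages.astype(float)
        Xz = (X - X.mean(axis=0)) / X.std(axis=0)
        pos = contrast_cohort.positions
        klass = contrast_cohort.vtable["class"].to_numpy()

        def mean_proxies(idxs, nmax=250):
            sel = np.random.default_rng(1).choice(
                idxs, size=min(nmax, idxs.size), replace=False
            )
            out = []
            for i in sel:
                lo = np.searchsorted(pos, pos[i] - 100_000)
                hi = np.searchsorted(pos, pos[i] + 100_000)
                idx = np.arange(lo, hi)
                idx = idx[idx != i]
                if idx.size == 0:
                    out.append(0)
                    continue
                r = (Xz[:, idx].T @ Xz[:, i]) / Xz.shape[0]
                out.append(int((r * r > 0.8).sum()))
            return float(np.mean(out))

        common = mean_proxies(np.flatnonzero(klass == "common"))
        rare = mean_proxies(np.flatnonzero(klass == "rare"))
        assert common > rare


class TestGenotypes:
    def test_pair_sum(self):
        panel = HaplotypePanel(
            np.array([10, 20]), np.array([[0, 1], [1, 1], [0, 0], [0, 1]], dtype=np.uint8), 100
        )
        geno = haplotypes_to_genotypes(panel)
        assert np.array_equal(geno.dosages, [[1, 2], [0, 1]])

    def test_all_zero(self):
        panel = HaplotypePanel(np.array([5]), np.zeros((6, 1), dtype=np.uint8), 10)
        assert not haplotypes_to_genotypes(panel).dosages.any()

    def test_column_sums_conserved(self):
        panel = generate_founders(15, 80, 10_000, seed=2)
        geno = haplotypes_to_genotypes(panel)
        assert np.array_equal(
            geno.dosages.sum(axis=0), panel.alleles.sum(axis=0, dtype=np.int64)
        )

    def test_odd_haplotype_count_rejected(self):
        panel = HaplotypePanel(np.array([5]), np.zeros((3, 1), dtype=np.uint8), 10)
        with pytest.raises(ValueError, match="odd"):
            haplotypes_to_genotypes(panel)


def _panel_from_counts(counts, n_hap):
    """Toy panel whose site s has exactly counts[s] alternate alleles."""
    alleles = np.zeros((n_hap, len(counts)), dtype=np.uint8)
    for s, c in enumerate(counts):
        alleles[:c, s] = 1
    return HaplotypePanel(np.arange(1, len(counts) + 1), alleles, 1000)


class TestFilterVariants:
    def test_minor_allele_count_hand_count(self):
        """8 haplotypes, alternate counts (0,1,2,3,4,5,7,8): minor counts are
        (0,1,2,3,4,3,1,0), so min_mac=3 keeps exactly the 3 middle sites."""
        panel = _panel_from_counts([0, 1, 2, 3, 4, 5, 7, 8], 8)
        out, vt = filter_variants(panel, 3)
        assert out.n_sites == 3
        assert np.array_equal(out.allele_counts(), [3, 4, 5])

    def test_doubleton_removed_at_default(self):
        panel = _panel_from_counts([2, 3], 10)
        out, _ = filter_variants(panel, 3)
        assert np.array_equal(out.allele_counts(), [3])

    def test_min_mac_zero_is_identity(self):
        panel = _panel_from_counts([0, 1, 5, 10], 10)
        out, _ = filter_variants(panel, 0)
        assert out.n_sites == 4

    def test_classes_follow_maf_cutoffs(self):
        panel = generate_founders(200, 300, 100_000, seed=4, sfs_floor=0.001)
        _, vt = filter_variants(panel, 1)
        maf = vt["maf"].to_numpy()
        klass = vt["class"].to_numpy()
        assert np.all(klass[maf > 0.01] == "common")
        assert np.all(klass[(maf > 0.0003) & (maf <= 0.01)] == "rare")
        assert set(klass) >= {"common", "rare"}

    @given(
        counts=st.lists(st.integers(0, 12), min_size=1, max_size=8),
        min_mac=st.integers(0, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_filter_keeps_exactly_mac_ge_threshold(self, counts, min_mac):
        panel = _panel_from_counts(counts, 12)
        out, vt = filter_variants(panel, min_mac)
        expect = [c for c in counts if min(c, 12 - c) >= min_mac]
        assert list(out.allele_counts()) == expect
        assert len(vt) == out.n_sites


class TestLdR2:
    def test_identical_columns(self):
        geno = GenotypeMatrix(np.array([1, 2]), np.array([[0, 0], [1, 1], [2, 2]]))
        assert ld_r2(geno, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        geno = GenotypeMatrix(
            np.array([1, 2]), np.array([[0, 1], [0, 1], [1, 0], [1, 0]])
        )
        assert ld_r2(geno, 0, 1) == pytest.approx(1.0)

    def test_matches_brute_force_covariance(self):
        x = np.array([0.0, 1, 2, 1])
        y = np.array([0.0, 1, 1, 2])
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 4
        expected = (cov / (x.std() * y.std())) ** 2
        geno = GenotypeMatrix(np.array([1, 2]), np.c_[x, y])
        assert ld_r2(geno, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_rejected(self):
        geno = GenotypeMatrix(np.array([1, 2]), np.array([[0, 1], [0, 0], [0, 2]]))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(geno, 0, 1)


class TestVcfRoundTrip:
    def test_panel_survives_vcf(self, tmp_path):
        from gwasprec.io import read_vcf, write_vcf

        founders = generate_founders(12, 40, 80_000, seed=6)
        pop = generate_population(founders, 20, 1e-5, 1e-3, seed=7)
        path = tmp_path / "panel.vcf"
        write_vcf(pop, path)
        back = read_vcf(path)
        assert np.array_equal(back.positions, pop.positions)
        assert np.array_equal(back.alleles, pop.alleles)
        assert back.region_length == pop.region_length

    def test_variant_table_columns(self):
        panel = generate_founders(10, 30, 10_000, seed=8)
        vt = variant_table(panel)
        assert list(vt.columns) == ["position", "ac", "f", "maf", "class"]
        assert (vt["maf"] <= 0.5).all()
        assert np.allclose(vt["maf"], np.minimum(vt["f"], 1 - vt["f"]))
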