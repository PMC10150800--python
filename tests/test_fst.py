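"""Differentiation stage: variance components, HDS/HDG calls, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from admixpress import fst


def wc_oracle(counts):
    """Independent transcription of the 1984 two-allele variance components.

    Deliberately written as explicit per-population loops over the printed
    formulas, sharing no code with the implementation.
    """
    counts = [list(map(float, row)) for row in counts]
    r = len(counts)
    n = [sum(row) for row in counts]
    p = [(2 * row[0] + row[1]) / (2 * ni) for row, ni in zip(counts, n)]
    h = [row[1] / ni for row, ni in zip(counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        site = fst.weir_cockerham_fst(np.array([[50, 0, 0], [0, 0, 50]]))
        assert site.fst == pytest.approx(1.0)

    def test_identical_counts_give_nonpositive_estimate(self):
        site = fst.weir_cockerham_fst(np.array([[30, 40, 30], [30, 40, 30]]))
        assert site.a == pytest.approx(0.0, abs=1e-12) or site.a < 0
        assert site.fst <= 0

    def test_components_match_oracle_on_spec_table(self):
        counts = np.array([[30, 40, 30], [10, 20, 70]])
        site = fst.weir_cockerham_fst(counts)
        a, b, c = wc_oracle(counts)
        assert site.a == pytest.approx(a, abs=1e-12)
        assert site.b == pytest.approx(b, abs=1e-12)
        assert site.c == pytest.approx(c, abs=1e-12)
        assert site.fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_monomorphic_site_is_undefined_not_zero(self):
        site = fst.weir_cockerham_fst(np.array([[50, 0, 0], [30, 0, 0]]))
        assert site.fst is None and not site.defined

    def test_population_label_swap_invariance(self, rng):
        for _ in range(25):
            counts = rng.integers(0, 40, size=(2, 3)) + 1
            e1 = fst.weir_cockerham_fst(counts).fst
            e2 = fst.weir_cockerham_fst(counts[::-1]).fst
            assert e1 == pytest.approx(e2, abs=1e-12)

    def test_allele_label_swap_invariance(self, rng):
        for _ in range(25):
            counts = rng.integers(0, 40, size=(2, 3)) + 1
            e1 = fst.weir_cockerham_fst(counts).fst
            e2 = fst.weir_cockerham_fst(counts[:, ::-1]).fst
            assert e1 == pytest.approx(e2, abs=1e-12)

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            fst.weir_cockerham_fst(np.array([[0, 0, 0], [10, 10, 10]]))


class TestHdsHdg:
    @pytest.mark.parametrize("estimate,expected", [
        (0.21, True), (0.20, False), (-0.01, False),
    ])
    def test_hds_strict_threshold(self, estimate, expected):
        site = fst.SiteFst("s", 0.1, 0.1, 0.1, estimate)
        assert fst.classify_hds(site) is expected

    def test_undefined_site_cannot_be_classified(self):
        with pytest.raises(ValueError):
            fst.classify_hds(fst.SiteFst("s", 0, 0, 0, None))

    def test_single_site_gene_equals_site_estimate(self):
        sites = [fst.SiteFst("s1", 0.1, 0.2, 0.1, 0.25)]
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [100]})
        (g,) = fst.gene_fst(sites, genes, {"s1": ("chr1", 50)})
        assert g.mean_fst == pytest.approx(0.25)
        assert g.weighted_fst == pytest.approx(0.1 / 0.4)
        assert g.n_sites == 1

    def test_two_site_aggregation_arithmetic(self):
        s1 = fst.SiteFst("s1", 0.10, 0.05, 0.05, 0.10 / 0.20)
        s2 = fst.SiteFst("s2", 0.02, 0.18, 0.20, 0.02 / 0.40)
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [100]})
        (g,) = fst.gene_fst([s1, s2], genes,
                            {"s1": ("chr1", 10), "s2": ("chr1", 20)})
        assert g.mean_fst == pytest.approx((0.5 + 0.05) / 2)
        assert g.weighted_fst == pytest.approx((0.10 + 0.02) / (0.20 + 0.40))

    def test_hdg_requires_both_thresholds(self):
        g = fst.GeneFst("g", mean_fst=0.25, weighted_fst=0.18, n_sites=4)
        assert fst.classify_hdg(g) is False
        g2 = fst.GeneFst("g", mean_fst=0.25, weighted_fst=0.21, n_sites=4)
        assert fst.classify_hdg(g2) is True

    def test_gene_outside_sites_is_undefined(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr2"],
                              "start": [0], "end": [100]})
        (g,) = fst.gene_fst([fst.SiteFst("s1", 0.1, 0.1, 0.1, 0.3)], genes,
                            {"s1": ("chr1", 50)})
        assert not g.defined


class TestFisherEnrichment:
    def test_spec_table_against_hypergeometric_summation(self):
        odds, p = fst.fisher_enrichment(10, 5, 90, 895)
        assert odds == pytest.approx(10 * 895 / (5 * 90), rel=1e-12)
        # two-sided exact p: sum over k of P(K = k) <= P(K = observed),
        # K ~ Hypergeom(N = 1000, K_total = 15, n_draws = 100)
        dist = hypergeom(1000, 15, 100)
        p_obs = dist.pmf(10)
        expected = sum(dist.pmf(k) for k in range(16)
                       if dist.pmf(k) <= p_obs * (1 + 1e-12))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_identical_proportions_or_one(self):
        odds, p = fst.fisher_enrichment(10, 90, 20, 180)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_hits_in_set(self):
        odds, _ = fst.fisher_enrichment(0, 10, 50, 500)
        assert odds == 0.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fst.fisher_enrichment(0, 0, 0, 0)

    def test_matches_enumeration_on_small_margins(self, rng):
        # exhaustive hypergeometric enumeration on random tables with
        # margins <= 30
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            _, p = fst.fisher_enrichment(a, b, c, d)
            N, K, n = a + b + c + d, a + b, a + c
            dist = hypergeom(N, K, n)
            lo, hi = max(0, K + n - N), min(K, n)
            p_obs = dist.pmf(a)
            expected = sum(dist.pmf(k) for k in range(lo, hi + 1)
                           if dist.pmf(k) <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(expected, rel=1e-8)


def test_genomewide_estimator_tracks_model_f(rng):
    """Ratio-of-sums estimate recovers the divergence dial across F values."""
    from admixpress import sim
    for f_true in (0.05, 0.4):
        freqs = sim.simulate_ancestral_frequencies(2000, f_true, int(rng.integers(1 << 30)))
        he = sim.simulate_haplotypes(freqs["freq_east"], 150, 1, "haplotypes_east")
        hw = sim.simulate_haplotypes(freqs["freq_west"], 150, 1, "haplotypes_west")
        comp = fst.fst_from_haplotypes(he.haplotypes, hw.haplotypes)
        assert fst.genomewide_fst(comp) == pytest.approx(f_true, abs=0.03)
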