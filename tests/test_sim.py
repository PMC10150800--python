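"""Synthetic-data generator: distributions, mosaic structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixpress import qtl, sim
from admixpress.containers import EAST, WEST


class TestAncestralFrequencies:
    def test_zero_divergence_copies_base(self):
        t = sim.simulate_ancestral_frequencies(100, 0.0, seed=1)
        assert np.array_equal(t["freq_east"], t["base_freq"])
        assert np.array_equal(t["freq_west"], t["base_freq"])

    def test_fixed_base_stays_fixed(self):
        t = sim.simulate_ancestral_frequencies(
            50, 0.3, seed=1, base_freq_sampler=lambda rng, n: np.ones(n))
        assert (t["freq_east"] == 1).all() and (t["freq_west"] == 1).all()
        assert t["monomorphic"].all()

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_ancestral_frequencies(10, 1.0, seed=1)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_ancestral_frequencies(
                10, 0.2, seed=1, base_freq_sampler=lambda rng, n: np.full(n, 1.5))


class TestHaplotypes:
    def test_fixed_frequency_all_carriers(self):
        h = sim.simulate_haplotypes(np.ones(5), 10, seed=2)
        assert (h.haplotypes == 1).all()

    def test_sample_frequency_within_binomial_bounds(self):
        h = sim.simulate_haplotypes(np.full(200, 0.5), 1000, seed=2)
        se = np.sqrt(0.25 / 2000)
        freqs = h.allele_frequencies()
        assert np.all(np.abs(freqs - 0.5) < 3 * se + 1e-9) or \
            (np.abs(freqs - 0.5) >= 3 * se).mean() < 0.02
        assert abs(freqs.mean() - 0.5) < 3 * se

    def test_empty_panel_valid(self):
        h = sim.simulate_haplotypes(np.full(5, 0.4), 0, seed=2)
        assert h.n_haplotypes == 0 and h.n_sites == 5


class TestAdmixed:
    def _panels(self, n_sites=150, seed=4):
        fe = np.full(n_sites, 0.1)
        fw = np.full(n_sites, 0.9)
        he = sim.simulate_haplotypes(fe, 200, seed, "haplotypes_east")
        hw = sim.simulate_haplotypes(fw, 200, seed, "haplotypes_west")
        mp = np.linspace(0, 1, n_sites)
        return he, hw, mp

    def test_alpha_one_everything_western(self):
        he, hw, mp = self._panels()
        adm, track = sim.simulate_admixed(he, hw, 1.0, 10.0, mp, 20, seed=4)
        assert set(track["ancestry"]) == {WEST}
        # admixed frequencies match the western panel in expectation
        assert abs(adm.allele_frequencies().mean()
                   - hw.allele_frequencies().mean()) < 0.05

    def test_mixture_frequency_formula(self):
        he, hw, mp = self._panels()
        adm, _ = sim.simulate_admixed(he, hw, 0.5, 20.0, mp, 2000, seed=4)
        target = 0.5 * hw.allele_frequencies() + 0.5 * he.allele_frequencies()
        diff = adm.allele_frequencies() - target
        # per-site noise at 4000 mosaic haplotypes (donor sharing inflates
        # the iid-binomial floor sqrt(pq/4000) ~ 0.008 by a small factor)
        assert np.abs(diff).mean() < 0.03
        assert abs(diff.mean()) < 0.02

    def test_generations_zero_single_segment(self):
        he, hw, mp = self._panels()
        adm, track = sim.simulate_admixed(he, hw, 0.5, 0.0, mp, 30, seed=4)
        per_hap = track.groupby(["sample", "haplotype"]).size()
        assert (per_hap == 1).all()

    def test_mean_ancestry_fraction_converges_to_alpha(self):
        he, hw, mp = self._panels()
        adm, track = sim.simulate_admixed(he, hw, 0.3, 15.0, mp, 400, seed=4)
        east = sim.ancestry_at_sites(track, adm)
        assert east.mean() == pytest.approx(0.7, abs=0.03)

    def test_empty_panel_rejected(self):
        he, hw, mp = self._panels()
        empty = sim.simulate_haplotypes(np.full(150, 0.5), 0, 1)
        with pytest.raises(ValueError):
            sim.simulate_admixed(empty, hw, 0.5, 10.0, mp, 10, seed=1)


class TestExpression:
    def _cohort(self, seed=6, n=200):
        cfg = sim.SimConfig(n_anc_east=80, n_anc_west=80, n_admixed=n,
                            n_sites=60, n_genes=4, fst_sim=0.1, seed=seed)
        return sim.simulate_cohort(cfg)

    def test_noiseless_single_effect_exact(self):
        c = self._cohort()
        s = 30
        expr = sim.simulate_expression(c.hap_admixed, c.east_mask,
                                       [(0, s, 2.0, 2.0)], [], 2, 0.0, 9)
        d = c.hap_admixed.dosages()[:, s]
        assert expr.loc["G0000"].to_numpy() == pytest.approx(2.0 * d)
        assert (expr.loc["G0001"] == 0).all()

    def test_ancestry_specific_beta_recovered(self):
        c = self._cohort(n=200)
        s = 30
        expr = sim.simulate_expression(c.hap_admixed, c.east_mask,
                                       [(0, s, 1.0, 0.0)], [], 1, 0.3, 9)
        H = c.hap_admixed.haplotypes
        east_copies = ((H[:, s] == 1) & c.east_mask[:, s]).reshape(-1, 2).sum(1)
        west_copies = ((H[:, s] == 1) & ~c.east_mask[:, s]).reshape(-1, 2).sum(1)
        y = expr.loc["G0000"].to_numpy()
        X = np.column_stack([np.ones(len(y)), east_copies, west_copies])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = resid @ resid / (len(y) - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(coef[1] - 1.0) < 2 * se + 0.05
        assert abs(coef[2]) < 0.15

    def test_null_associations_uniform_p(self):
        c = self._cohort(n=150)
        expr = sim.simulate_expression(c.hap_admixed, c.east_mask, [], [],
                                       4, 1.0, 10)
        dos = c.hap_admixed.dosages()
        pvals = []
        for g in range(4):
            for s in range(60):
                res = qtl.associate(expr.iloc[g].to_numpy(),
                                    dos[:, s].astype(float))
                if res is not None:
                    pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_dimension_mismatch_rejected(self):
        c = self._cohort()
        with pytest.raises(ValueError):
            sim.simulate_expression(c.hap_admixed, c.east_mask,
                                    [(99, 0, 1.0, 1.0)], [], 4, 1.0, 9)


class TestAseCounts:
    def _het(self, n=1000):
        return pd.DataFrame({"sample": ["s"] * n,
                             "site": [f"v{i}" for i in range(n)]})

    def test_balanced_truth_centers_on_half(self):
        counts = sim.simulate_ase_counts(self._het(), 0.0, 50.0, seed=3)
        frac = counts["ref_count"] / (counts["ref_count"] + counts["alt_count"])
        assert frac.mean() == pytest.approx(0.5, abs=0.01)

    def test_full_imbalance_monoallelic(self):
        counts = sim.simulate_ase_counts(self._het(100), 0.5, 30.0, seed=3)
        assert (counts["alt_count"] == 0).all()

    def test_depths_truncated_at_one(self):
        counts = sim.simulate_ase_counts(self._het(500), 0.1, 1.5, seed=3)
        assert ((counts["ref_count"] + counts["alt_count"]) >= 1).all()

    def test_mean_ai_recovery(self):
        counts = sim.simulate_ase_counts(self._het(1000), 0.2, 50.0, seed=3)
        frac = counts["ref_count"] / (counts["ref_count"] + counts["alt_count"])
        ai = np.abs(frac - 0.5)
        se = ai.std() / np.sqrt(len(ai))
        assert abs(ai.mean() - 0.2) < 3 * se + 0.002

    def test_invalid_ai_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_ase_counts(self._het(10), 0.7, 30.0, seed=3)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = dict(n_anc_east=30, n_anc_west=30, n_admixed=20, n_sites=80,
                   n_genes=4, fst_sim=0.2, seed=42)
        c1 = sim.simulate_cohort(sim.SimConfig(**cfg))
        c2 = sim.simulate_cohort(sim.SimConfig(**cfg))
        assert np.array_equal(c1.hap_admixed.haplotypes, c2.hap_admixed.haplotypes)
        assert c1.ancestry_track.equals(c2.ancestry_track)
        assert c1.expression.equals(c2.expression)

    def test_substreams_are_independent_of_each_other(self):
        # regenerating one component does not depend on whether another
        # component was drawn first
        f1 = sim.simulate_ancestral_frequencies(50, 0.2, seed=5)
        _ = sim.simulate_haplotypes(np.full(10, 0.5), 5, seed=5)
        f2 = sim.simulate_ancestral_frequencies(50, 0.2, seed=5)
        assert f1.equals(f2)
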