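"""EHH/iHH/iHS: pair-counting, integration, standardization, sweep flags."""

import itertools

import numpy as np
import pytest

from admixpress import selection


def ehh_enumeration_oracle(haplotypes, core_site, core_allele, direction):
    """Exhaustive pairwise-identity enumeration of EHH (independent oracle).

    For every offset, EHH = fraction of distinct carrier pairs identical
    over every site between the core and the offset (inclusive). Missing
    alleles (negative) never match anything.
    """
    H = np.asarray(haplotypes)
    carriers = [h for h in H if h[core_site] == core_allele]
    n = len(carriers)
    if n < 2:
        return None
    idx = (list(range(core_site + 1, H.shape[1])) if direction == +1
           else list(range(core_site - 1, -1, -1)))
    values = [1.0]
    for stop, _ in enumerate(idx):
        span = idx[: stop + 1]
        same = 0
        for h1, h2 in itertools.combinations(carriers, 2):
            ok = all(h1[j] == h2[j] and h1[j] >= 0 and h2[j] >= 0 for j in span)
            same += ok
        values.append(same / (n * (n - 1) / 2))
    return np.array(values)


class TestEhh:
    def test_core_offset_is_one(self, rng):
        H = rng.integers(0, 2, (10, 6)).astype(np.int8)
        H[:, 2] = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
        curve = selection.ehh(H, 2, 1, +1)
        assert curve.offsets[0] == 0 and curve.ehh[0] == 1.0

    def test_identical_carriers_stay_at_one(self):
        H = np.vstack([np.tile([1, 0, 1, 1, 0], (4, 1)),
                       np.tile([0, 1, 0, 0, 1], (3, 1))]).astype(np.int8)
        curve = selection.ehh(H, 0, 1, +1)
        assert np.all(curve.ehh == 1.0)

    def test_two_one_one_split(self):
        # 4 carriers whose extensions split 2/1/1 -> EHH = C(2,2)/C(4,2) = 1/6
        H = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 0, 1],
        ], dtype=np.int8)
        curve = selection.ehh(H, 0, 1, +1)
        assert curve.ehh[2] == pytest.approx(1 / 6)

    def test_fewer_than_two_carriers_undefined(self):
        H = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)
        assert selection.ehh(H, 0, 1, +1) is None

    def test_matches_enumeration_on_random_panels(self, rng):
        for _ in range(30):
            n_hap = int(rng.integers(4, 12))
            n_sites = int(rng.integers(3, 8))
            H = rng.integers(0, 2, (n_hap, n_sites)).astype(np.int8)
            core = int(rng.integers(n_sites))
            for allele in (0, 1):
                for direction in (+1, -1):
                    oracle = ehh_enumeration_oracle(H, core, allele, direction)
                    curve = selection.ehh(H, core, allele, direction)
                    if oracle is None:
                        assert curve is None
                        continue
                    assert curve.ehh == pytest.approx(oracle, abs=1e-12)

    def test_monotone_non_increasing(self, rng):
        for _ in range(10):
            H = rng.integers(0, 2, (20, 15)).astype(np.int8)
            curve = selection.ehh(H, 7, 1, +1)
            if curve is not None:
                assert np.all(np.diff(curve.ehh) <= 1e-12)

    def test_missing_allele_breaks_extension(self):
        H = np.array([
            [1, 1, 1],
            [1, 1, 1],
            [1, -1, 1],
        ], dtype=np.int8)
        curve = selection.ehh(H, 0, 1, +1)
        # only the two complete haplotypes stay identical: 1 pair of 3
        assert curve.ehh[1] == pytest.approx(1 / 3)


class TestIhh:
    def test_no_decay_integrates_full_length_with_flag(self):
        curve = selection.EhhCurve(0, 1, np.array([0.0, 0.4, 1.0]),
                                   np.array([1.0, 1.0, 1.0]))
        val, truncated = selection.ihh(curve)
        assert val == pytest.approx(1.0)
        assert truncated

    def test_hand_integration_with_interpolated_crossing(self):
        # EHH 1 at 0 cM, 0.5 at 0.1 cM, 0.04 at 0.2 cM; cutoff 0.05
        curve = selection.EhhCurve(0, 1, np.array([0.0, 0.001, 0.002]),
                                   np.array([1.0, 0.5, 0.04]))
        val, truncated = selection.ihh(curve, cutoff=0.05)
        xc = 0.001 + (0.5 - 0.05) / (0.5 - 0.04) * 0.001
        expected = 0.5 * (1.0 + 0.5) * 0.001 + 0.5 * (0.5 + 0.05) * (xc - 0.001)
        assert val == pytest.approx(expected, abs=1e-15)
        assert not truncated

    def test_immediate_drop_single_partial_trapezoid(self):
        curve = selection.EhhCurve(0, 1, np.array([0.0, 0.01]),
                                   np.array([1.0, 0.0]))
        val, truncated = selection.ihh(curve, cutoff=0.05)
        xc = (1.0 - 0.05) / 1.0 * 0.01
        assert val == pytest.approx(0.5 * (1.0 + 0.05) * xc)
        assert not truncated


class TestIhs:
    def test_equal_integrals_give_zero(self):
        assert selection.ihs_unstandardized(0.3, 0.3) == 0.0

    def test_zero_integral_rejected(self):
        with pytest.raises(ValueError):
            selection.ihs_unstandardized(0.0, 0.3)

    def test_standardized_scores_unit_moments_per_bin(self, rng):
        daf = rng.uniform(0.05, 0.95, 4000)
        vals = rng.normal(0.5 * daf, 1.0)   # frequency-dependent mean
        z = selection.standardize_ihs(vals, daf, n_bins=20)
        edges = np.linspace(0, 1, 21)
        for b in range(20):
            m = (daf >= edges[b]) & (daf < edges[b + 1]) & ~np.isnan(z)
            if m.sum() >= 10:
                assert np.mean(z[m]) == pytest.approx(0.0, abs=0.15)
                assert np.std(z[m]) == pytest.approx(1.0, abs=0.15)

    def test_extreme_daf_excluded(self):
        z = selection.standardize_ihs([0.1, 0.2, 0.3, 0.4],
                                      [0.01, 0.5, 0.5, 0.99])
        assert np.isnan(z[0]) and np.isnan(z[3])

    def test_sweep_flag_strict(self):
        assert selection.flag_sweep(2.44)
        assert selection.flag_sweep(-2.44)
        assert not selection.flag_sweep(2.0)


def make_sweep_panel(rng, n_hap=60, n_sites=41, carriers=24):
    """Neutral panel with one long shared haplotype among derived carriers."""
    freq = rng.uniform(0.2, 0.8, n_sites)
    H = (rng.random((n_hap, n_sites)) < freq).astype(np.int8)
    core = n_sites // 2
    H[:, core] = 0
    shared = (rng.random(n_sites) < freq).astype(np.int8)
    H[:carriers] = shared          # identical extended haplotype
    H[:carriers, core] = 1         # all carry the derived core allele
    return H, core


def test_sweep_fixture_yields_large_negative_raw_ihs(rng):
    """A long shared derived haplotype inflates iHH_derived, so the raw
    log-ratio ln(iHH_a/iHH_d) goes strongly negative; shuffling each
    column destroys the signal."""
    H, core = make_sweep_panel(rng)
    mp = np.linspace(0, 0.4, H.shape[1])
    res_d = selection.ihh_site(H, core, 1, mp)
    res_a = selection.ihh_site(H, core, 0, mp)
    raw_sweep = selection.ihs_unstandardized(res_a[0], res_d[0])

    controls = []
    for _ in range(20):
        Hs = H.copy()
        for j in range(H.shape[1]):
            if j != core:
                Hs[:, j] = rng.permutation(Hs[:, j])
        rd = selection.ihh_site(Hs, core, 1, mp)
        ra = selection.ihh_site(Hs, core, 0, mp)
        controls.append(selection.ihs_unstandardized(ra[0], rd[0]))
    controls = np.array(controls)
    assert raw_sweep < controls.min()
    assert raw_sweep < controls.mean() - 4 * controls.std(ddof=1)
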