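import numpy as np
import pandas as pd
import pytest

from methylseries.core import FeatureSet, GenomicInterval, Methylome
from methylseries.tfbs import (
    focal_delta,
    half_width_at_half_depth,
    histone_delta_profile,
    neighborhood_profile,
    site_methylation,
)
from tests.conftest import make_site_matrix


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def methylome_with_levels(pos, levels, label="s"):
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "meth_count": 0,
            "total_count": 10,
        }
    )
    m = Methylome(label, df)
    m.sites["level"] = levels
    return m


class TestSiteMethylation:
    def test_mean_of_contained_cpgs(self):
        m = methylome_with_levels([100, 150, 500], [0.2, 0.4, 0.9])
        assert site_methylation(iv(50, 200), m) == pytest.approx(0.3)

    def test_cpg_free_site_is_missing(self):
        m = methylome_with_levels([100], [0.5])
        assert np.isnan(site_methylation(iv(300, 400), m))

    def test_random_sites_match_naive_scan(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(100_000, 2000, replace=False))
        lv = rng.random(2000)
        m = methylome_with_levels(pos, lv)
        for _ in range(200):
            s = int(rng.integers(0, 99_000))
            e = s + int(rng.integers(10, 2000))
            expect = [l for p, l in zip(pos, lv) if s <= p < e]
            got = site_methylation(iv(s, e), m)
            if expect:
                assert got == pytest.approx(np.mean(expect))
            else:
                assert np.isnan(got)


class TestFocalDelta:
    def test_identical_samples_zero_delta(self, series):
        pos = np.arange(50) * 20
        lv = np.tile(np.linspace(0.1, 0.9, 50)[:, None], (1, 6))
        sm = make_site_matrix(pos, lv, series.labels)
        fs = FeatureSet("tf", [iv(0, 200), iv(400, 600)])
        fd = focal_delta(fs, sm, series)
        assert fd.per_sample_delta == pytest.approx(np.zeros(6), abs=1e-12)

    def test_planted_drop_recovered(self, series):
        pos = np.arange(100) * 10
        lv = np.full((100, 6), 0.8)
        j = series.labels.index("ESC")
        lv[20:40, j] = 0.3
        sm = make_site_matrix(pos, lv, series.labels)
        fd = focal_delta(FeatureSet("tf", [iv(200, 400)]), sm, series)
        assert fd.per_sample_delta[j] == pytest.approx(-0.5)
        assert fd.per_sample_delta[0] == pytest.approx(0.0)

    def test_pairwise_missing_sites_excluded(self, series):
        pos = np.arange(10) * 10
        lv = np.full((10, 6), 0.5)
        sm = make_site_matrix(pos, lv, series.labels)
        sm.levels[0:5, 1] = np.nan  # site 1 missing in sample D2
        sm.levels[5:10, 1] = 0.9
        fd = focal_delta(FeatureSet("tf", [iv(0, 50), iv(50, 100)]), sm, series)
        assert fd.n_sites_used[1] == 1
        assert fd.per_sample_delta[1] == pytest.approx(0.4)

    def test_all_sites_missing_is_error(self, series):
        sm = make_site_matrix(np.arange(5) * 10, np.full((5, 6), 0.5), series.labels)
        with pytest.raises(ValueError):
            focal_delta(FeatureSet("tf", [iv(5000, 6000)]), sm, series)


class TestNeighborhoodProfile:
    def test_uniform_difference_gives_flat_profile(self, series):
        pos = np.arange(2000) * 100
        lv = np.full((2000, 6), 0.7)
        j = series.labels.index("IPS")
        lv[:, j] = 0.5
        sm = make_site_matrix(pos, lv, series.labels)
        prof = neighborhood_profile(
            FeatureSet("tf", [iv(99_000, 99_200), iv(150_000, 150_200)]), sm, series,
            bin_width=200, n_bins=100,
        )
        filled = ~np.isnan(prof.delta_matrix[:, j])
        assert filled.any()
        assert prof.delta_matrix[filled, j] == pytest.approx(-0.2, abs=1e-12)

    def test_single_cpg_at_midpoint_lands_in_center_bin(self, series):
        # one site, one CpG exactly at the midpoint: bin n_bins/2
        pos = np.array([10_000])
        lv = np.full((1, 6), 0.5)
        lv[0, 5] = 0.9
        sm = make_site_matrix(pos, lv, series.labels)
        prof = neighborhood_profile(
            FeatureSet("tf", [iv(9_900, 10_100)]), sm, series, bin_width=200, n_bins=20
        )
        filled = np.flatnonzero(~np.isnan(prof.delta_matrix[:, 5]))
        assert filled.tolist() == [10]
        assert prof.delta_matrix[10, 5] == pytest.approx(0.4)
        assert prof.n_sites_contributing[10] == 1

    def test_symmetric_kernel_gives_symmetric_profile(self, series):
        """A symmetric demethylation kernel around each site yields mirror-
        image left/right bin means up to sampling noise."""
        rng = np.random.default_rng(0)
        pos = np.arange(8000) * 50
        lv = np.full((8000, 6), 0.8)
        j = series.labels.index("ESC")
        mids = np.array([100_000, 200_000, 300_000])
        for mid in mids:
            d = pos - mid
            lv[:, j] -= 0.6 * np.exp(-(d**2) / (2 * 1000.0**2))
        lv = np.clip(lv + rng.normal(0, 0.01, lv.shape), 0, 1)
        sm = make_site_matrix(pos, lv, series.labels)
        prof = neighborhood_profile(
            FeatureSet("tf", [iv(int(m) - 100, int(m) + 100) for m in mids]),
            sm, series, bin_width=200, n_bins=40,
        )
        left = prof.delta_matrix[:20, j]
        right = prof.delta_matrix[20:, j][::-1]
        assert np.nanmax(np.abs(left - right)) < 0.05


def oracle_coverage_fraction(s, e, peaks):
    """bp-resolution oracle for window coverage by merged peaks."""
    covered = np.zeros(e - s, dtype=bool)
    for ps, pe in peaks:
        lo, hi = max(ps, s), min(pe, e)
        if lo < hi:
            covered[lo - s : hi - s] = True
    return covered.mean()


class TestHistoneProfile:
    def _peaks(self, by_sample, series):
        return {
            lab: FeatureSet(lab, [iv(s, e) for s, e in by_sample.get(lab, [])])
            for lab in series.labels
        }

    def test_identical_peak_sets_zero_delta(self, series):
        peaks = self._peaks({lab: [(0, 500)] for lab in series.labels}, series)
        fd = histone_delta_profile(peaks, FeatureSet("tf", [iv(100, 400)]), series)
        assert fd.per_sample_delta == pytest.approx(np.zeros(6), abs=1e-12)

    def test_full_gain_gives_plus_one(self, series):
        by = {lab: [] for lab in series.labels}
        by["ESC"] = [(0, 1000)]
        fd = histone_delta_profile(
            self._peaks(by, series), FeatureSet("tf", [iv(100, 400), iv(500, 800)]), series
        )
        j = series.labels.index("ESC")
        assert fd.per_sample_delta[j] == pytest.approx(1.0)
        assert fd.per_sample_delta[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_focal_score_matches_bp_oracle(self, series, seed):
        rng = np.random.default_rng(seed)
        peaks = {
            lab: [
                (int(s), int(s + l))
                for s, l in zip(rng.integers(0, 5000, 30), rng.integers(10, 400, 30))
            ]
            for lab in series.labels
        }
        site = iv(1000, 1990)  # 33 windows of 30 bp
        fd = histone_delta_profile(self._peaks(peaks, series), FeatureSet("tf", [site]), series)
        # oracle: mean over 30-bp windows of bp coverage, delta vs baseline
        expect = []
        for lab in series.labels:
            scores = []
            for ws in range(site.start, site.end, 30):
                we = min(ws + 30, site.end)
                scores.append(oracle_coverage_fraction(ws, we, peaks[lab]))
            expect.append(np.mean(scores))
        expect = np.array(expect) - expect[0]
        assert fd.per_sample_delta == pytest.approx(expect, abs=1e-12)

    def test_neighborhood_mode_bins(self, series):
        by = {lab: [] for lab in series.labels}
        by["ESC"] = [(9_000, 11_000)]
        prof = histone_delta_profile(
            self._peaks(by, series),
            FeatureSet("tf", [iv(9_950, 10_050)]),
            series,
            mode="neighborhood",
            bin_width=200,
            n_bins=20,
        )
        j = series.labels.index("ESC")
        assert prof.delta_matrix[10, j] == pytest.approx(1.0)
        assert prof.delta_matrix[0, j] == pytest.approx(0.0)


class TestHalfWidth:
    def test_gaussian_dip_half_width(self):
        x = (np.arange(400) - 200) * 200.0
        sd = 2000.0
        delta = -0.6 * np.exp(-(x**2) / (2 * sd**2))
        hw = half_width_at_half_depth(delta, 200)
        # FWHM/2 = 1.1774 sd
        assert hw == pytest.approx(1.1774 * sd, rel=0.15)

    def test_flat_profile_has_no_width(self):
        assert half_width_at_half_depth(np.zeros(100), 200) is None
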