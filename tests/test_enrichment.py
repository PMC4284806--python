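import numpy as np
import pytest

from methylseries.core import FeatureSet, GenomicInterval
from methylseries.enrichment import (
    containment_table,
    fold_enrichment,
    methylation_stratified_marks,
    predict_important_tfs,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def oracle_containment(regions, features):
    """Naive O(n*m) overlap scan."""
    out = []
    for r in regions:
        out.append(
            any(
                f.chrom == r.chrom and f.start < r.end and r.start < f.end
                for f in features.intervals
            )
        )
    return np.mean(out)


class TestFoldEnrichment:
    def test_identity_when_region_is_the_reference(self):
        feats = FeatureSet("f", [iv(i * 100, i * 100 + 10) for i in range(10)])
        regions = [iv(0, 1000)]
        res = fold_enrichment(feats, regions, reference_bp=1000, reference_count=10)
        assert res.fold == pytest.approx(1.0)

    def test_printed_formula(self):
        # 1,000 bp reference holding 10 features; a 100 bp region holding 5
        feats = FeatureSet("f", [iv(s, s + 2) for s in range(0, 100, 20)])
        res = fold_enrichment(feats, [iv(0, 100)], reference_bp=1000, reference_count=10)
        assert res.observed_count == 5 and res.region_bp == 100
        assert res.fold == pytest.approx((5 / 100) / (10 / 1000))

    def test_region_bp_uses_merged_union(self):
        feats = FeatureSet("f", [iv(0, 10)])
        res = fold_enrichment(feats, [iv(0, 100), iv(50, 150)], 1000, 1)
        assert res.region_bp == 150

    def test_zero_reference_count_flags_undefined_fold(self):
        feats = FeatureSet("f", [iv(0, 10)])
        res = fold_enrichment(feats, [iv(0, 100)], 1000, 0)
        assert res.fold is None and res.containment_frac == 1.0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(FeatureSet("f", []), [], 1000, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_uniform_random_features_give_unit_fold_on_average(self, seed):
        """Features scattered uniformly are unenriched: mean fold ~ 1."""
        rng = np.random.default_rng(seed)
        genome = 100_000
        regions = [iv(20_000, 30_000), iv(60_000, 75_000)]
        folds = []
        for _ in range(300):
            starts = rng.integers(0, genome - 5, 80)
            feats = FeatureSet("f", [iv(int(s), int(s) + 5) for s in starts])
            res = fold_enrichment(feats, regions, reference_bp=genome, reference_count=80)
            folds.append(res.fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)


class TestContainment:
    def test_full_and_zero_containment(self):
        regions = [iv(0, 100), iv(200, 300)]
        full = FeatureSet("f", [iv(0, 300)])
        none = FeatureSet("g", [iv(1000, 1100)])
        t = containment_table(regions, [full, none])
        assert t["f"] == 1.0 and t["g"] == 0.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_naive_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        regions = [iv(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 50_000, 150), rng.integers(10, 800, 150))]
        feats = FeatureSet("f", [iv(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 50_000, 200), rng.integers(5, 300, 200))])
        t = containment_table(regions, [feats])
        assert t["f"] == pytest.approx(oracle_containment(regions, feats))

    def test_invariant_under_splitting_features(self):
        regions = [iv(0, 100), iv(500, 700), iv(900, 905)]
        whole = FeatureSet("f", [iv(50, 650)])
        split = FeatureSet("f", [iv(50, 200), iv(200, 400), iv(400, 650)])
        a = containment_table(regions, [whole])["f"]
        b = containment_table(regions, [split])["f"]
        assert a == b


class FakeDMR:
    def __init__(self, interval):
        self.interval = interval


class TestStratifiedMarks:
    def test_full_association_in_low_stratum(self):
        dmrs = [FakeDMR(iv(0, 100)), FakeDMR(iv(200, 300))]
        lv = np.array([[0.1], [0.1]])
        k4 = FeatureSet("k4", [iv(0, 300)])
        k27 = FeatureSet("k27", [iv(0, 300)])
        t = methylation_stratified_marks(dmrs, lv, k4, k27)
        assert t.loc["low", "both"] == 1.0
        assert t.loc["high", "n_pairs"] == 0

    def test_no_overlap_gives_none_fraction_one(self):
        dmrs = [FakeDMR(iv(0, 100))]
        t = methylation_stratified_marks(
            dmrs, np.array([[0.9]]), FeatureSet("k4", [iv(500, 600)]), FeatureSet("k27", [])
        )
        assert t.loc["high", "none"] == 1.0

    def test_coupled_generator_fraction_recovered(self):
        """Marks planted over low-methylation DMRs with probability 0.95."""
        rng = np.random.default_rng(0)
        dmrs, k4_iv, k27_iv, lv = [], [], [], []
        for i in range(800):
            s = i * 1000
            dmrs.append(FakeDMR(iv(s, s + 200)))
            low = rng.random() < 0.5
            lv.append([0.1 if low else 0.9])
            p = 0.95 if low else 0.05
            if rng.random() < p:
                k4_iv.append(iv(s + 50, s + 150))
                k27_iv.append(iv(s + 50, s + 150))
        t = methylation_stratified_marks(
            dmrs, np.array(lv), FeatureSet("k4", k4_iv), FeatureSet("k27", k27_iv)
        )
        assert t.loc["low", "both"] == pytest.approx(0.95, abs=0.03)
        assert t.loc["high", "none"] == pytest.approx(0.95, abs=0.03)


class TestTfSelection:
    def _make(self, containment, fold_boost, dmr3, all_dmrs, rng, n_sites=40):
        """Factor sites hitting a chosen fraction of DMR-3 regions, with the
        remainder scattered over the other DMRs at a density set by
        fold_boost."""
        sites = []
        n_in = int(round(containment * len(dmr3)))
        for r in dmr3[:n_in]:
            sites.append(iv(r.start + 10, r.start + 30))
        others = [r for r in all_dmrs if r not in dmr3]
        n_out = max(int(round(n_in / max(fold_boost, 1e-9))) - n_in, 0)
        for k in range(min(n_out, len(others))):
            r = others[k]
            sites.append(iv(r.start + 10, r.start + 30))
        return FeatureSet(f"tf_c{containment}_f{fold_boost}", sites)

    def test_constructed_selection(self):
        rng = np.random.default_rng(0)
        all_dmrs = [iv(i * 10_000, i * 10_000 + 1000) for i in range(100)]
        dmr3 = all_dmrs[:20]
        strong = self._make(0.5, 4.0, dmr3, all_dmrs, rng)
        weak_overlap = self._make(0.05, 4.0, dmr3, all_dmrs, rng)
        weak_fold = FeatureSet(
            "uniform", [iv(r.start + 10, r.start + 30) for r in all_dmrs]
        )
        out = predict_important_tfs([strong, weak_overlap, weak_fold], dmr3, all_dmrs)
        sel = dict(zip(out["factor"], out["selected"]))
        assert sel[strong.feature_name]
        assert not sel[weak_overlap.feature_name]
        assert not sel[weak_fold.feature_name]  # fold ~ 1 everywhere

    def test_all_sites_in_dmr3_selected_and_none_rejected(self):
        all_dmrs = [iv(i * 10_000, i * 10_000 + 1000) for i in range(50)]
        dmr3 = all_dmrs[:10]
        inside = FeatureSet("in", [iv(r.start, r.end) for r in dmr3])
        outside = FeatureSet("out", [iv(r.start, r.end) for r in all_dmrs[10:]])
        out = predict_important_tfs([inside, outside], dmr3, all_dmrs)
        sel = dict(zip(out["factor"], out["selected"]))
        assert sel["in"] and not sel["out"]

    def test_empty_site_set_skipped(self):
        all_dmrs = [iv(0, 100)]
        out = predict_important_tfs([FeatureSet("empty", [])], all_dmrs, all_dmrs)
        assert len(out) == 0

    def test_selection_monotone_in_overlap(self):
        """Adding DMR-3 hits to a selected factor never deselects it."""
        all_dmrs = [iv(i * 10_000, i * 10_000 + 1000) for i in range(60)]
        dmr3 = all_dmrs[:15]
        base_sites = [iv(r.start, r.end) for r in dmr3[:5]]
        fs = FeatureSet("tf", list(base_sites))
        out = predict_important_tfs([fs], dmr3, all_dmrs)
        assert out["selected"].iloc[0]
        for extra in range(5, 15):
            fs.intervals.append(iv(dmr3[extra].start, dmr3[extra].end))
            out = predict_important_tfs([fs], dmr3, all_dmrs)
            assert out["selected"].iloc[0]
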