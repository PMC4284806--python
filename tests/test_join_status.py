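import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from methylseries.core import SampleSeries
from methylseries.dmr import (
    DMR,
    archetype_templates,
    classify_status,
    cluster_dmrs,
    dmr_accumulation,
    join_windows,
)
from methylseries.core import GenomicInterval


def oracle_join(recs, frac=0.60):
    """Independent merge oracle: repeated O(n^2)/restart application of the
    two join rules (>= 1 bp overlap; then the gap-below-(1-frac)*min rule on
    consecutive sorted regions) until nothing changes."""
    regions = sorted([[c, s, e] for c, s, e in recs], key=lambda r: (r[0], r[1], r[2]))
    # overlap closure
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(len(regions)):
                if i == j:
                    continue
                a, b = regions[i], regions[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    del regions[j]
                    changed = True
                    break
            if changed:
                break
    # gap rule on consecutive regions, restart on first merge
    changed = True
    while changed:
        changed = False
        regions.sort(key=lambda r: (r[0], r[1]))
        for i in range(len(regions) - 1):
            a, b = regions[i], regions[i + 1]
            if a[0] != b[0]:
                continue
            gap = b[1] - a[2]
            if gap < (1 - frac) * min(a[2] - a[1], b[2] - b[1]):
                a[2] = max(a[2], b[2])
                del regions[i + 1]
                changed = True
                break
    return [(c, s, e) for c, s, e in regions]


def random_windows(rng, n):
    starts = rng.integers(0, 50_000, n)
    lengths = rng.integers(50, 3000, n)
    chroms = rng.choice(["chr1", "chr2"], n)
    return [(c, int(s), int(s + l)) for c, s, l in zip(chroms, starts, lengths)]


class TestJoinWindows:
    def test_overlap_merges(self):
        out = join_windows([("chr1", 0, 1000), ("chr1", 500, 1500)])
        assert len(out) == 1
        assert (out[0]["start"], out[0]["end"]) == (0, 1500)
        assert sorted(out[0]["members"]) == [0, 1]

    def test_distant_windows_stay_apart(self):
        out = join_windows([("chr1", 0, 1000), ("chr1", 11_000, 12_000)])
        assert len(out) == 2

    def test_gap_rule_bridges_near_regions(self):
        # gap 300 < 0.4 * min(1000, 1000)
        out = join_windows([("chr1", 0, 1000), ("chr1", 1300, 2300)])
        assert len(out) == 1

    def test_chromosomes_never_merge(self):
        out = join_windows([("chr1", 0, 1000), ("chr2", 0, 1000)])
        assert len(out) == 2

    @pytest.mark.parametrize("seed", list(range(6)))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_windows(rng, int(rng.integers(2, 200)))
        got = [(r["chrom"], r["start"], r["end"]) for r in join_windows(recs)]
        assert sorted(got) == sorted(oracle_join(recs))

    @given(st.lists(st.tuples(st.integers(0, 20_000), st.integers(10, 2000)), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        recs = [("chr1", s, s + l) for s, l in raw]
        once = join_windows(recs)
        again = join_windows([(r["chrom"], r["start"], r["end"]) for r in once])
        assert [(r["chrom"], r["start"], r["end"]) for r in once] == [
            (r["chrom"], r["start"], r["end"]) for r in again
        ]

    def test_progressing_rule_uses_left_region(self):
        # gap 300: progressing region 1000 long -> bridge; small left -> not
        assert len(join_windows([("chr1", 0, 1000), ("chr1", 1300, 1400)], rule="progressing")) == 1
        assert len(join_windows([("chr1", 900, 1000), ("chr1", 1300, 2300)], rule="progressing")) == 2


class TestClassifyStatus:
    def test_hyper_hypo_and_strict_boundary(self, series):
        levels = {"MEF": 0.10, "D2": 0.35, "D8": 0.10, "F1": 0.30, "IPS": 0.05, "ESC": 0.31}
        st_ = classify_status(levels, series, delta=0.20)
        assert st_["D2"] == "hyper"  # 0.25 > 0.20
        assert st_["F1"] == "none"  # exactly 0.20, strict
        assert st_["ESC"] == "hyper"  # 0.21 > 0.20

    def test_hypo(self, series):
        levels = {l: 0.9 for l in series.labels}
        levels["ESC"] = 0.65
        assert classify_status(levels, series)["ESC"] == "hypo"

    def test_degenerate_deltas(self, series):
        rng = np.random.default_rng(0)
        levels = {l: float(rng.random()) for l in series.labels}
        assert set(classify_status(levels, series, delta=1.0).values()) == {"none"}
        st0 = classify_status(levels, series, delta=0.0)
        assert all(v in ("hyper", "hypo") for v in st0.values())

    def test_missing_baseline_is_error(self, series):
        with pytest.raises(ValueError):
            classify_status({"D2": 0.5}, series)


class TestClusterDmrs:
    def test_planted_archetypes_recovered(self, series):
        rng = np.random.default_rng(0)
        templates = archetype_templates(series)
        chosen = ["DMR-1a", "DMR-2b", "DMR-3"]
        rows, labels = [], []
        for lab in chosen:
            base = 0.1 + 0.7 * templates[lab]
            for _ in range(50):
                rows.append(np.clip(base + rng.normal(0, 0.05, len(base)), 0, 1))
                labels.append(lab)
        out = cluster_dmrs(np.array(rows), series, n_groups=3)
        assert adjusted_rand_score(labels, out["cluster_id"]) >= 0.9
        # archetype naming agrees with the planted trajectory
        acc = np.mean(out["group_label"].to_numpy() == np.array(labels))
        assert acc >= 0.9

    def test_identical_rows_share_a_group(self, series):
        row = np.array([0.1, 0.2, 0.4, 0.6, 0.9, 0.9])
        out = cluster_dmrs(np.stack([row, row, row * 0.9 + 0.05]), series, n_groups=2)
        assert out["cluster_id"][0] == out["cluster_id"][1]

    def test_single_group(self, series):
        rng = np.random.default_rng(1)
        rows = 0.1 + 0.7 * archetype_templates(series)["DMR-3"] + rng.normal(0, 0.02, (10, 6))
        out = cluster_dmrs(rows, series, n_groups=1)
        assert set(out["cluster_id"]) == {1}

    def test_flat_rows_get_nearest_archetype_without_clustering(self, series):
        rows = np.vstack([np.full(6, 0.5), 0.1 + 0.7 * archetype_templates(series)["DMR-1a"]])
        out = cluster_dmrs(rows, series, n_groups=2)
        assert out["cluster_id"][0] == -1
        assert out["group_label"][0] in archetype_templates(series)


class TestAccumulation:
    def _dmr(self, status):
        return DMR(
            interval=GenomicInterval("chr1", 0, 10),
            member_windows=[],
            per_sample_levels={},
            status_by_sample=status,
        )

    def test_counts_concentrate_in_last_sample(self, series):
        ds = [
            self._dmr({l: ("hyper" if l == "ESC" else "none") for l in series.labels[1:]})
            for _ in range(5)
        ]
        counts, _ = dmr_accumulation(ds, series)
        assert counts.loc["ESC", "hyper"] == 5
        assert counts.drop("ESC")["hyper"].sum() == 0

    def test_identical_status_gives_full_sharing(self, series):
        ds = [
            self._dmr({l: "hypo" for l in series.labels[1:]}),
            self._dmr({l: "hypo" for l in series.labels[1:]}),
        ]
        _, sharing = dmr_accumulation(ds, series, sharing_pairs=[("IPS", "ESC")])
        assert sharing[("IPS", "ESC", "hypo")] == 1.0
        assert np.isnan(sharing[("IPS", "ESC", "hyper")])

    def test_partial_sharing_fraction(self, series):
        a = {l: "hyper" for l in series.labels[1:]}
        b = dict(a)
        b["ESC"] = "none"
        ds = [self._dmr(a), self._dmr(a), self._dmr(b), self._dmr(b)]
        _, sharing = dmr_accumulation(ds, series, sharing_pairs=[("IPS", "ESC")])
        assert sharing[("IPS", "ESC", "hyper")] == pytest.approx(0.5)

    def test_gradual_gain_counts_nondecreasing(self, series):
        """Monotone-gain trajectories yield non-decreasing hyper counts along
        the time-course."""
        rng = np.random.default_rng(2)
        templates = archetype_templates(series)
        course = [l for l in series.labels if l != "MEF" and l not in series.esc_like_labels]
        ds = []
        for lab in ("DMR-1a", "DMR-1b"):
            base = 0.1 + 0.7 * templates[lab]
            for _ in range(30):
                lv = dict(zip(series.labels, np.clip(base + rng.normal(0, 0.02, 6), 0, 1)))
                ds.append(
                    self._dmr(classify_status(lv, series))
                )
        counts, _ = dmr_accumulation(ds, series)
        hyper = counts.loc[list(course), "hyper"].to_numpy()
        assert all(b >= a for a, b in zip(hyper, hyper[1:]))
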