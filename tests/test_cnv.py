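"""CNV calling: ratio algebra, segmentation (with brute-force oracle),
cutoff calls, focal biallelic detection, recurrence."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import thymoclone as tc
from thymoclone import cnv
from thymoclone.cnv import (
    AMPLIFICATION,
    DELETION,
    NEUTRAL,
    CnvSegment,
    OutOfModelError,
    _best_arc,
    _segment_breaks,
    percent,
)
from conftest import uniform_exons


# ---------------------------------------------------------------------------
# algebra


class TestAlgebra:
    @given(
        f=st.floats(min_value=0.01, max_value=1.0),
        delta=st.sampled_from([-2, -1, 1, 2, 3]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, f, delta):
        c = cnv.ratio_from_cell_fraction(f, delta)
        assert cnv.cell_fraction_from_ratio(c, delta) == pytest.approx(f, abs=1e-12)

    def test_zero_ratio_maps_to_zero_fraction_for_any_delta(self):
        for delta in (-2, -1, 1, 2):
            assert cnv.cell_fraction_from_ratio(0.0, delta) == 0.0

    def test_out_of_model_ratio_flagged(self):
        with pytest.raises(OutOfModelError):
            cnv.cell_fraction_from_ratio(-1.2, -1)

    def test_zero_copy_change_rejected(self):
        with pytest.raises(ValueError):
            cnv.cell_fraction_from_ratio(-0.3, 0)

    def test_percent_rounds_half_away_from_zero(self):
        assert percent(0.375) == 38
        assert percent(0.2974) == 30
        assert percent(0.295) == 30


# ---------------------------------------------------------------------------
# log ratios


class TestLogRatios:
    def test_equal_depths_give_zero_everywhere(self):
        exons = uniform_exons(20)
        exons["tumor_depth"] = 100.0
        exons["normal_depth"] = 100.0
        out = cnv.compute_log_ratios(exons)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_halved_tumor_depth_is_minus_one(self):
        exons = uniform_exons(5)
        exons["tumor_depth"] = 50.0
        exons["normal_depth"] = 100.0
        out = cnv.compute_log_ratios(exons, pseudocount=1e-9, normalize=False)
        assert np.allclose(out["log2_ratio"], -1.0, atol=1e-6)

    def test_library_size_normalization_removes_depth_difference(self):
        exons = uniform_exons(10)
        exons["tumor_depth"] = 400.0  # twice the normal library
        exons["normal_depth"] = 200.0
        out = cnv.compute_log_ratios(exons, normalize=True)
        assert np.allclose(out["log2_ratio"], 0.0, atol=1e-9)

    def test_all_zero_normal_rejected(self):
        exons = uniform_exons(5)
        exons["tumor_depth"] = 10.0
        exons["normal_depth"] = 0.0
        with pytest.raises(ValueError, match="normal"):
            cnv.compute_log_ratios(exons)

    def test_chr_y_excluded_when_flagged(self):
        exons = pd.concat([uniform_exons(5), uniform_exons(3, chromosome="chrY")])
        exons["tumor_depth"] = 100.0
        exons["normal_depth"] = 100.0
        out = cnv.compute_log_ratios(exons, exclude_chr_y=True)
        assert set(out["chromosome"]) == {"chr1"}


# ---------------------------------------------------------------------------
# segmentation oracles


def oracle_best_arc(x, min_seg):
    """O(n^2) scan for the max |pooled-t| circular arc, via scipy."""
    x = np.asarray(x, float)
    n = len(x)
    if n < max(3, 2 * min_seg):
        return None
    best = None
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            if len(inside) < min_seg or len(outside) < min_seg:
                continue
            ss = np.sum((inside - inside.mean()) ** 2) + np.sum(
                (outside - outside.mean()) ** 2
            )
            if ss <= 1e-12 * (1.0 + np.mean(x * x)):
                t = math.inf if abs(inside.mean() - outside.mean()) > 1e-9 else 0.0
            elif len(inside) >= 2 and len(outside) >= 2:
                t = abs(stats.ttest_ind(inside, outside, equal_var=True).statistic)
            else:
                # scipy's t-test needs >= 2 observations per group; fall back
                # to the pooled-t formula for single-exon arcs
                se = math.sqrt(ss / (n - 2) * (1 / len(inside) + 1 / len(outside)))
                t = abs(inside.mean() - outside.mean()) / se
            if best is None or t > best[0]:
                best = (t, i, j)
    if best is None or best[0] <= 0:
        return None
    return best


def oracle_segment(x, alpha, min_seg, n_perm, rng):
    """Independent recursive segmentation with its own permutation rng."""
    breaks = set()

    def rec(lo, hi):
        seg = np.asarray(x[lo:hi], float)
        res = oracle_best_arc(seg, min_seg)
        if res is None:
            return
        tobs, i, j = res
        exceed = 0
        for _ in range(n_perm):
            r = oracle_best_arc(rng.permutation(seg), min_seg)
            if r is not None and r[0] >= tobs:
                exceed += 1
        if (1 + exceed) / (1 + n_perm) >= alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        if not cuts:
            return
        breaks.update(lo + c for c in cuts)
        bounds = sorted({0, *cuts, hi - lo})
        for a, b in zip(bounds[:-1], bounds[1:]):
            rec(lo + a, lo + b)

    rec(0, len(x))
    return sorted(breaks)


def segment_frame(x, chromosome="chr1"):
    n = len(x)
    return pd.DataFrame(
        {
            "chromosome": [chromosome] * n,
            "start": np.arange(n),
            "end": np.arange(n) + 1,
            "log2_ratio": np.asarray(x, float),
        }
    )


class TestSegmentation:
    @pytest.mark.parametrize("min_seg", [1, 2])
    def test_best_arc_matches_bruteforce(self, min_seg):
        rng = np.random.default_rng(42)
        for n in range(4, 13):
            x = rng.normal(size=n)
            mine = _best_arc(x, min_seg)
            ref = oracle_best_arc(x, min_seg)
            assert mine is not None and ref is not None
            t_m, i_m, j_m = mine
            t_r, i_r, j_r = ref
            assert t_m == pytest.approx(t_r, rel=1e-9)
            # an arc and its complement induce the same cuts; compare those
            cuts = lambda i, j: {c for c in (i, j) if 0 < c < n}
            assert cuts(i_m, j_m) == cuts(i_r, j_r)

    def test_noise_free_breakpoint_recovered_exactly(self):
        x = np.r_[np.zeros(50), -np.ones(50)]
        segs = tc.segment_log_ratios(segment_frame(x), seed=0)
        assert [(s.first_exon, s.last_exon) for s in segs] == [(0, 49), (50, 99)]
        assert segs[0].mean_log2_ratio == 0.0
        assert segs[1].mean_log2_ratio == -1.0

    def test_tiny_inputs_match_exhaustive_recursive_oracle(self):
        rng = np.random.default_rng(5)
        cases = []
        # overwhelming steps: the permutation decision cannot be borderline
        for _ in range(5):
            left = rng.normal(0.0, 0.05, 6)
            right = rng.normal(5.0, 0.05, 6)
            cases.append((np.r_[left, right], 0.05))
        # alpha below the attainable permutation floor: never splits
        for _ in range(5):
            cases.append((rng.normal(0.0, 1.0, 12), 1e-4))
        for x, alpha in cases:
            mine = _segment_breaks(
                x, alpha=alpha, min_seg=2, n_perm=199, rng=np.random.default_rng(1)
            )
            ref = oracle_segment(
                x, alpha=alpha, min_seg=2, n_perm=199, rng=np.random.default_rng(2)
            )
            assert mine == ref

    def test_pure_noise_rarely_splits(self):
        # false-split rate per chromosome should track alpha
        n_seg = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0.0, 0.1, 100)
            segs = tc.segment_log_ratios(
                segment_frame(x), alpha=0.01, n_permutations=200, seed=seed
            )
            n_seg.append(len(segs))
        assert min(n_seg) >= 1
        assert np.mean(n_seg) <= 1.25

    def test_segments_partition_and_means_match(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 0.1, 40), rng.normal(-0.8, 0.1, 30),
                  rng.normal(0.4, 0.1, 30)]
        frame = segment_frame(x)
        segs = tc.segment_log_ratios(frame, seed=0)
        assert sum(s.n_exons for s in segs) == 100
        covered = sorted(
            (s.first_exon, s.last_exon) for s in segs
        )
        assert covered[0][0] == 0 and covered[-1][1] == 99
        for (a, b), (c, _) in zip(covered[:-1], covered[1:]):
            assert c == b + 1
        for s in segs:
            assert s.mean_log2_ratio == pytest.approx(
                x[s.first_exon : s.last_exon + 1].mean()
            )

    def test_low_permutation_count_warns(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(UserWarning, match="unstable"):
            tc.segment_log_ratios(segment_frame(x), n_permutations=50, seed=0)

    def test_same_seed_reproduces_segmentation(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.normal(0, 0.2, 60), rng.normal(-0.6, 0.2, 40)]
        frame = segment_frame(x)
        a = tc.segment_log_ratios(frame, seed=4)
        b = tc.segment_log_ratios(frame, seed=4)
        assert a == b


# ---------------------------------------------------------------------------
# calling and cell-fraction recovery


def make_segment(mean, chrom="chr1", first=0, last=9):
    return CnvSegment(
        chromosome=chrom,
        first_exon=first,
        last_exon=last,
        start=first,
        end=last + 1,
        n_exons=last - first + 1,
        mean_log2_ratio=mean,
    )


class TestCalling:
    def test_cutoff_boundaries_inclusive(self):
        called, _ = cnv.call_segments([make_segment(-0.3), make_segment(0.2)])
        assert [s.call for s in called] == [DELETION, AMPLIFICATION]

    def test_neutral_zero(self):
        called, counts = cnv.call_segments([make_segment(0.0)])
        assert called[0].call == NEUTRAL
        assert counts["total"] == 0

    def test_three_way_calls(self):
        called, counts = cnv.call_segments(
            [make_segment(m) for m in (-0.5, 0.1, 0.25)]
        )
        assert [s.call for s in called] == [DELETION, NEUTRAL, AMPLIFICATION]
        assert counts == {DELETION: 1, AMPLIFICATION: 1, NEUTRAL: 1, "total": 2}

    def test_called_fractions_invert_the_model(self):
        called, _ = cnv.call_segments([make_segment(-0.3), make_segment(0.2)])
        assert called[0].cell_fraction == pytest.approx(0.3755, abs=5e-4)
        assert called[1].cell_fraction == pytest.approx(0.2974, abs=5e-4)

    def test_deep_deletion_out_of_model_under_single_copy(self):
        called, _ = cnv.call_segments([make_segment(-3.0)])
        assert called[0].call == DELETION
        assert called[0].out_of_model
        assert called[0].cell_fraction is None

    def test_lowering_del_cutoff_never_adds_deletions(self):
        rng = np.random.default_rng(0)
        segs = [make_segment(m) for m in rng.uniform(-1.5, 1.0, 50)]
        prev = None
        for cutoff in (-0.1, -0.3, -0.6, -1.0):
            _, counts = cnv.call_segments(segs, del_cutoff=cutoff)
            if prev is not None:
                assert counts[DELETION] <= prev
            prev = counts[DELETION]


class TestFractionRecovery:
    def test_median_error_small_across_seeds(self):
        # 100-exon lesion at 200x depth; lesion mean ratio inverted under
        # the simulated copy change
        for f, delta in [(0.2, -1), (0.38, -1), (0.5, -1), (0.98, -2)]:
            errs = []
            for seed in range(100):
                exons = uniform_exons(100)
                cfg = tc.CoverageSimConfig(
                    exon_table=exons,
                    mean_depth=200,
                    lesions=[tc.Lesion("chr1", 0, int(exons["end"].max()), delta, f)],
                    seed=seed,
                )
                lr = tc.compute_log_ratios(tc.simulate_coverage(cfg), normalize=False)
                c = lr["log2_ratio"].mean()
                f_hat = cnv.cell_fraction_from_ratio(c, delta)
                errs.append(abs(f_hat - f))
            assert np.median(errs) < 0.03, (f, delta)


class TestFocalBiallelic:
    @staticmethod
    def _simulated_ratios(delta, f, seed=0):
        exons = uniform_exons(60)
        lesion = tc.Lesion("chr1", 20 * 2000, 30 * 2000, delta, f)
        cfg = tc.CoverageSimConfig(
            exon_table=exons, mean_depth=200, lesions=[lesion], seed=seed
        )
        return tc.compute_log_ratios(tc.simulate_coverage(cfg), normalize=False)

    def test_near_clonal_biallelic_deletion_flagged(self):
        lr = self._simulated_ratios(-2, 0.98)
        regions = cnv.detect_focal_biallelic_deletion(lr)
        assert len(regions) == 1
        assert regions[0].cell_fraction == pytest.approx(0.98, abs=0.02)
        assert regions[0].first_exon >= 18 and regions[0].last_exon <= 31

    def test_no_lesion_gives_empty_list(self):
        lr = self._simulated_ratios(-2, 0.98)
        lr["log2_ratio"] = 0.0
        assert cnv.detect_focal_biallelic_deletion(lr) == []

    def test_het_deletion_not_flagged(self):
        # ratio -0.30 sits far above the biallelic floor
        lr = self._simulated_ratios(-1, 0.38)
        assert cnv.detect_focal_biallelic_deletion(lr) == []


class TestRecurrence:
    @staticmethod
    def _tumor(amplified, n=40):
        """One-chromosome partition with a single amplified interval."""
        first, last = amplified
        segs = []
        bounds = sorted({0, first, last + 1, n})
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean = 0.4 if (a, b - 1) == (first, last) else 0.0
            segs.append(make_segment(mean, first=a, last=b - 1))
        called, _ = cnv.call_segments(segs)
        return called

    def test_full_overlap(self):
        sets = [self._tumor((10, 20)) for _ in range(3)]
        regions = cnv.recurrent_regions(sets)
        assert [(r.first_exon, r.last_exon, r.call) for r in regions] == [
            (10, 20, AMPLIFICATION)
        ]

    def test_disjoint_calls_give_empty_result(self):
        regions = cnv.recurrent_regions([self._tumor((0, 5)), self._tumor((20, 30))])
        assert regions == []

    def test_partial_overlaps_intersect(self):
        sets = [self._tumor((10, 20)), self._tumor((15, 25)), self._tumor((12, 18))]
        regions = cnv.recurrent_regions(sets)
        assert [(r.first_exon, r.last_exon) for r in regions] == [(15, 18)]

    def test_mismatched_exon_tables_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cnv.recurrent_regions(
                [self._tumor((10, 20), n=40), self._tumor((10, 20), n=50)]
            )


class TestCoverageIO:
    def test_bed_plus_depths_round_trip(self, tmp_path):
        exons = uniform_exons(10)
        exons[["chromosome", "start", "end"]].to_csv(
            tmp_path / "e.bed", sep="\t", index=False, header=False
        )
        dep = pd.DataFrame(
            {
                "exon_index": np.arange(10),
                "tumor_depth": np.arange(10) + 100,
                "normal_depth": np.full(10, 200),
            }
        )
        dep.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        out = cnv.read_coverage(tmp_path / "e.bed", tmp_path / "d.tsv")
        assert out["tumor_depth"].tolist() == list(range(100, 110))

    def test_missing_depth_column_named(self, tmp_path):
        exons = uniform_exons(3)
        exons[["chromosome", "start", "end"]].to_csv(
            tmp_path / "e.bed", sep="\t", index=False, header=False
        )
        pd.DataFrame({"exon_index": [0, 1, 2], "tumor_depth": [1, 2, 3]}).to_csv(
            tmp_path / "d.tsv", sep="\t", index=False
        )
        with pytest.raises(ValueError, match="normal_depth"):
            cnv.read_coverage(tmp_path / "e.bed", tmp_path / "d.tsv")
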