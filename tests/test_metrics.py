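import numpy as np
import pandas as pd
import pytest

import rofseg as rs
from rofseg.metrics import (_Agg, _nearest_rank_quantile, round_half_up,
                            match_percentages)


class TestUnitConversion:
    def test_single_pixel(self):
        assert rs.px_to_um2(1) == pytest.approx(0.2025)

    def test_roi_area(self):
        assert round_half_up(rs.px_to_mm2(900 * 600), 3) == 0.109

    @pytest.mark.parametrize("px,um2", [
        (753.3, 152.5), (659.8, 133.6), (829.2, 167.9)])
    def test_mean_hull_sizes(self, px, um2):
        assert round_half_up(rs.px_to_um2(px), 1) == um2

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rs.px_to_um2(-1)


def _agg(count, eval_mm2, nuclei=0.0, hull_px=0):
    eval_px = int(round(eval_mm2 * 1e6 / 0.45 ** 2))
    return _Agg(count=count, hull_area_px=hull_px, eval_area_px=eval_px,
                nuclei_estimate=nuclei, pixel_size_um=0.45)


class TestSampleMetrics:
    def test_density(self):
        m = rs.sample_metrics(_agg(100, 0.5))
        assert m.density == pytest.approx(200.0, rel=1e-6)

    def test_cell_percentage(self):
        m = rs.sample_metrics(_agg(50, 1.0, nuclei=1000))
        assert m.cell_percentage == pytest.approx(5.0)

    def test_area_percentage(self):
        eval_px = 1000000
        agg = _Agg(count=1, hull_area_px=50000, eval_area_px=eval_px,
                   nuclei_estimate=0.0, pixel_size_um=0.45)
        m = rs.sample_metrics(agg)
        assert m.area_percentage == pytest.approx(5.0)

    def test_zero_denominators_flagged_none(self):
        m = rs.sample_metrics(_Agg(0, 0, 0, 0.0, 0.45))
        assert m.density is None
        assert m.cell_percentage is None
        assert m.area_percentage is None

    def test_scale_consistency(self):
        m1 = rs.sample_metrics(_agg(100, 0.5))
        m2 = rs.sample_metrics(_agg(200, 1.0))
        assert m1.density == pytest.approx(m2.density)


class TestSubsampleTiles:
    def _tiles(self, counts):
        return [_agg(c, 0.1) for c in counts]

    def test_rate_1_is_identity(self):
        tiles = self._tiles([3, 5, 2, 7])
        full = rs.subsample_tiles(tiles, 1.0)
        assert full.count == 17
        assert full.density == pytest.approx(17 / 0.4, rel=1e-6)

    def test_stride_half_takes_every_second_tile(self):
        tiles = self._tiles([3, 5, 2, 7])
        m = rs.subsample_tiles(tiles, 0.5, mode="stride")
        assert m.count == 3 + 2

    def test_stride_quarter(self):
        tiles = self._tiles(list(range(8)))
        m = rs.subsample_tiles(tiles, 0.25, mode="stride")
        assert m.count == 0 + 4

    def test_seeded_random_is_reproducible(self):
        tiles = self._tiles(list(range(16)))
        m1 = rs.subsample_tiles(tiles, 0.5, mode="seeded-random", seed=7)
        m2 = rs.subsample_tiles(tiles, 0.5, mode="seeded-random", seed=7)
        assert m1.count == m2.count

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            rs.subsample_tiles(self._tiles([1]), 0.3)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = rs.pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = rs.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r, _ = rs.pearson_r(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rs.pearson_r([1, 1, 1], [1, 2, 3])


def _result_with_hull(hull_slices, shape=(120, 120)):
    conv = np.zeros(shape, bool)
    for sl in hull_slices:
        conv[sl] = True
    return rs.SegmentationResult(
        features=[], i_eval=np.ones(shape, bool),
        i_segm=conv.copy(), i_conv=conv, count=len(hull_slices),
        hull_area_px=int(conv.sum()), eval_area_px=conv.size,
        nuclei_estimate=0.0, initial_threshold=0, params=rs.RuleParams())


def _tag_mask_at(centers, shape=(120, 120)):
    mask = np.zeros(shape, bool)
    for r, c in centers:
        mask[r, c] = True
        mask[r - 1, c] = mask[r + 1, c] = mask[r, c - 1] = mask[r, c + 1] = True
    return mask


class TestExactMatchValidation:
    def test_tag_inside_hull_matches(self):
        res = _result_with_hull([(slice(40, 60), slice(40, 60))])
        report = rs.exact_match_validation(_tag_mask_at([(50, 50)]), res)
        assert report.n_matched == 1 and report.pct_of_tags == 100.0

    def test_distant_tag_unmatched(self):
        res = _result_with_hull([(slice(0, 10), slice(0, 10))])
        report = rs.exact_match_validation(_tag_mask_at([(110, 110)]), res,
                                           proximity_px=10)
        assert report.n_matched == 0

    def test_tag_exactly_at_proximity_matches(self):
        res = _result_with_hull([(slice(40, 60), slice(40, 60))])
        # hull ends at row 59; center at row 59 + 7 is Chebyshev-7 away
        report = rs.exact_match_validation(_tag_mask_at([(66, 50)]), res,
                                           proximity_px=7)
        assert report.n_matched == 1
        report = rs.exact_match_validation(_tag_mask_at([(67, 50)]), res,
                                           proximity_px=7)
        assert report.n_matched == 0

    def test_proximity_zero_matches_are_subset(self, rng):
        res = _result_with_hull([(slice(30, 50), slice(30, 50)),
                                 (slice(80, 100), slice(20, 40))])
        centers = [(int(r), int(c)) for r, c in
                   rng.integers(5, 115, size=(20, 2))]
        tight = rs.exact_match_validation(_tag_mask_at(centers), res, 0)
        loose = rs.exact_match_validation(_tag_mask_at(centers), res, 10)
        assert tight.n_matched <= loose.n_matched

    def test_unique_matching_caps_per_hull(self):
        res = _result_with_hull([(slice(40, 60), slice(40, 60))])
        tags = _tag_mask_at([(45, 45), (50, 50), (55, 55)])
        lumped = rs.exact_match_validation(tags, res)
        assert lumped.n_matched == 3          # all tags hit the one hull
        unique = rs.exact_match_validation(tags, res, unique=True)
        assert unique.n_matched == 1

    def test_percentage_bases(self):
        res = _result_with_hull([(slice(40, 60), slice(40, 60)),
                                 (slice(0, 10), slice(100, 110))])
        tags = _tag_mask_at([(50, 50), (55, 55), (90, 10), (20, 20)])
        report = rs.exact_match_validation(tags, res, proximity_px=3)
        assert (report.n_tags, report.n_features, report.n_matched) == (4, 2, 2)
        assert report.pct_of_tags == 50.0
        assert report.pct_of_features == 100.0


class TestMatchPercentages:
    def test_recount_consistency(self, rng):
        tags = int(rng.integers(50, 200))
        feats = int(rng.integers(40, 180))
        matched = int(rng.integers(1, min(tags, feats)))
        pct = match_percentages(tags, feats, matched)
        assert pct["pct_matched_of_tags"] == pytest.approx(100 * matched / tags)
        assert pct["pct_matched_of_features"] == pytest.approx(
            100 * matched / feats)


class TestSizeDistribution:
    def _results(self, sizes, doubles):
        feats = []
        for s, d in zip(sizes, doubles):
            from rofseg.geometry import Feature
            f = Feature(rows=np.zeros(1, int), cols=np.zeros(1, int),
                        bbox=(0, 0, 1, 1))
            f.s, f.c, f.double_stained = s, float(s) * 1.2, d
            feats.append(f)
        res = _result_with_hull([])
        res.features = feats
        return [res]

    def test_basic_statistics(self):
        table = rs.size_distribution(self._results(
            [160, 200, 600], [False, False, False]))
        row = table[(table.subpopulation == "all") &
                    (table.measure == "feature")].iloc[0]
        assert row["mean"] == pytest.approx(320)
        assert row["median"] == 200

    def test_all_double_leaves_single_empty(self):
        table = rs.size_distribution(self._results([200, 300], [True, True]))
        row = table[(table.subpopulation == "single") &
                    (table.measure == "feature")].iloc[0]
        assert row["n"] == 0
        assert row["mean"] is None or np.isnan(row["mean"])

    def test_q95_nearest_rank_oracle(self, rng):
        sizes = rng.integers(160, 1500, size=1000)
        table = rs.size_distribution(self._results(
            sizes.tolist(), [False] * 1000))
        row = table[(table.subpopulation == "all") &
                    (table.measure == "feature")].iloc[0]
        srt = np.sort(sizes)
        assert row["q95"] == srt[int(np.ceil(0.95 * 1000)) - 1]

    def test_subpopulations_partition(self):
        table = rs.size_distribution(self._results(
            [200, 300, 400, 500], [True, False, True, False]))
        get = lambda sub: int(table[(table.subpopulation == sub) &
                                    (table.measure == "feature")].iloc[0]["n"])
        assert get("all") == get("single") + get("double")

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            rs.size_distribution([_result_with_hull([])])


class TestGeneExpressionNormalization:
    def _table(self):
        genes = list(rs.HOUSEKEEPERS) + ["TARGET"]
        return pd.DataFrame([[9] * 10 + [10]], columns=genes,
                            index=["sample1"])

    def test_equal_housekeepers_give_simple_divisor(self):
        norm = rs.normalize_gene_expression(self._table())
        # housekeepers all 9 -> divisor 10; target (10+1)/10*1000 = 1100
        assert norm.loc["sample1", "TARGET"] == pytest.approx(1100.0)
        assert norm.loc["sample1", "B2M"] == pytest.approx(1000.0)

    def test_matches_log_space_oracle(self, rng):
        genes = list(rs.HOUSEKEEPERS) + ["G1", "G2"]
        counts = pd.DataFrame(rng.integers(1, 500, size=(5, len(genes))),
                              columns=genes)
        norm = rs.normalize_gene_expression(counts)
        shifted = counts + 1.0
        for i in counts.index:
            div = np.exp(np.mean([np.log(shifted.loc[i, g])
                                  for g in rs.HOUSEKEEPERS]))
            assert norm.loc[i, "G1"] == pytest.approx(
                shifted.loc[i, "G1"] / div * 1000)

    def test_missing_housekeeper_rejected(self):
        with pytest.raises(ValueError):
            rs.normalize_gene_expression(
                pd.DataFrame({"B2M": [1.0], "TARGET": [2.0]}))
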