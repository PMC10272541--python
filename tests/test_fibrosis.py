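import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shgquant import (
    AnalysisConfig,
    ChannelImage,
    DegenerateHistogramError,
    RegionMaskSet,
    classify_strings,
    compute_fibrosis_params,
    extract_strings,
    otsu_threshold,
    segment_collagen,
)
from shgquant.fibrosis import CollagenMask

PS = 0.390625


def brute_force_otsu(hist):
    """Exhaustive between-class-variance maximization (the oracle)."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    levels = np.arange(len(hist))
    best_t, best_v = None, -1.0
    for t in range(len(hist) - 1):
        w0 = hist[: t + 1].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / (w0 * total)
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / (w1 * total)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def test_otsu_two_spike_histogram_separates_classes():
    hist = np.zeros(256)
    hist[10] = 100
    hist[200] = 100
    t = otsu_threshold(hist)
    assert 10 <= t < 200


def test_otsu_single_bin_is_degenerate():
    hist = np.zeros(256)
    hist[42] = 1000
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(hist)


@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_otsu_matches_brute_force_on_random_histograms(seed):
    rng = np.random.default_rng(seed)
    hist = rng.integers(0, 50, size=256)
    if (hist > 0).sum() < 2:
        hist[[3, 200]] = 5
    assert otsu_threshold(hist) == brute_force_otsu(hist)


def test_segment_collagen_rectangle_stencil_oracle():
    shape = (256, 256)
    shg = np.full(shape, 5, np.uint8)
    shg[50:114, 40:91] = 200  # 64 x 51 = 3264 px of 65536 = 4.98%
    mask = segment_collagen(ChannelImage(shg, PS, "SHG"), np.ones(shape, bool))
    assert mask.area_pct == pytest.approx(100 * 3264 / 65536, abs=0.2)
    assert mask.mask.sum() == 3264


def test_segment_all_background_returns_empty_with_warning():
    shg = ChannelImage(np.full((64, 64), 8, np.uint8), PS, "SHG")
    with pytest.warns(UserWarning, match="degenerate"):
        mask = segment_collagen(shg, np.ones((64, 64), bool))
    assert mask.degenerate and not mask.mask.any() and mask.area_pct == 0.0


def test_collagen_mask_confined_to_tissue(small_sample):
    mask = segment_collagen(small_sample.shg, small_sample.regions.tissue)
    assert 0 <= mask.area_pct <= 100
    assert not (mask.mask & ~small_sample.regions.tissue).any()


def _strings_from_mask(mask, pixel_size_um=PS, regions=None):
    if regions is None:
        regions = RegionMaskSet.from_tissue(np.ones(mask.shape, bool))
    collagen = CollagenMask(mask=mask, threshold=0, area_pct=100 * mask.mean())
    return extract_strings(collagen, regions, pixel_size_um)


def test_horizontal_bar_length_matches_analytic_value():
    mask = np.zeros((64, 512), bool)
    mask[32, 128:384] = True  # 256 px -> 100 um
    (s,) = _strings_from_mask(mask)
    assert s.length_um == pytest.approx(100.0, rel=0.02)
    assert s.n_branch_points == 0


def test_thick_bar_width_is_area_over_length():
    mask = np.zeros((64, 512), bool)
    mask[30:35, 128:384] = True  # 5 px thick
    (s,) = _strings_from_mask(mask)
    assert s.mean_width_um == pytest.approx(5 * PS, rel=0.15)


def test_plus_shape_has_branch_points():
    mask = np.zeros((64, 64), bool)
    mask[32, 10:54] = True
    mask[10:54, 32] = True
    (s,) = _strings_from_mask(mask)
    assert s.n_branch_points >= 1


def test_lengths_scale_with_pixel_size():
    mask = np.zeros((32, 128), bool)
    mask[16, 10:110] = True
    (s1,) = _strings_from_mask(mask, pixel_size_um=1.0)
    (s2,) = _strings_from_mask(mask, pixel_size_um=2.0)
    assert s2.length_um == pytest.approx(2 * s1.length_um)
    assert s2.mean_width_um == pytest.approx(2 * s1.mean_width_um)


def test_empty_mask_gives_no_strings():
    assert _strings_from_mask(np.zeros((32, 32), bool)) == []


def _flagged(length_um, width_um, centroid, region="PS"):
    from shgquant.fibrosis import CollagenString

    return CollagenString(
        component_id=0, skeleton=np.zeros((0, 2), int), centroid=centroid,
        area_um2=length_um * width_um, length_um=length_um, mean_width_um=width_um,
        region=region, n_branch_points=0, pixels=np.zeros((0, 2), int),
    )


def test_classify_strings_rule_application():
    iso = _flagged(100.0, 0.4, (10.0, 10.0))
    trio = [_flagged(10.0, 0.4, (200.0, 200.0 + i * 10)) for i in range(3)]
    strings = classify_strings([iso] + trio, AnalysisConfig(), pixel_size_um=1.0)
    assert strings[0].is_long and strings[0].is_thin and strings[0].is_distributed
    assert all(s.is_aggregated for s in strings[1:])
    # shrinking the aggregation radius to (almost) zero distributes everything
    tiny = classify_strings([iso] + trio, AnalysisConfig(agg_radius_um=1e-9), pixel_size_um=1.0)
    assert all(s.is_distributed for s in tiny)


def test_classify_strings_rejects_nonpositive_thresholds():
    with pytest.raises(Exception):
        classify_strings([_flagged(10, 1, (0, 0))], AnalysisConfig(long_min_um=-1))


def test_param_counting_and_subset_inequalities():
    strings = classify_strings(
        [_flagged(100.0, 0.4, (i * 100.0, 50.0)) for i in range(5)],
        AnalysisConfig(),
        pixel_size_um=1.0,
    )
    collagen = CollagenMask(np.zeros((8, 8), bool), 0, 0.0)
    params = compute_fibrosis_params(strings, collagen)
    assert params["#LongStrPS"] == 5 and params["#ThinStrPS"] == 5
    assert params["#ThinStrPSAgg"] == 0 and params["#LongStrPSDis"] == 5
    assert params["#ThinStrPSAgg"] <= params["#ThinStrPS"]
    assert params["#LongStrPSDis"] <= params["#LongStrPS"]
    empty = compute_fibrosis_params([], collagen)
    assert empty["#Str"] == 0 and empty["CPA"] == 0.0


def test_subset_inequalities_on_synthetic_sample(small_sample):
    collagen = segment_collagen(small_sample.shg, small_sample.regions.tissue)
    strings = classify_strings(
        extract_strings(collagen, small_sample.regions, PS),
        pixel_size_um=PS,
    )
    params = compute_fibrosis_params(strings, collagen, small_sample.regions)
    assert params["#ThinStrPSAgg"] <= params["#ThinStrPS"]
    assert params["#LongStrPSDis"] <= params["#LongStrPS"]
    assert params["#StrCV"] + params["#StrPT"] + params["#StrPS"] == params["#Str"]
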