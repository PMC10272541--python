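import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from shgquant import (
    AnalysisConfig,
    RegionMaskSet,
    classify_strings,
    coloc_params,
    colocalize,
    compute_fibrosis_params,
    extract_strings,
    segment_collagen,
)
from shgquant.fibrosis import CollagenMask
from shgquant.steatosis import SteatosisParams

PS = 0.390625


def _steatosis(shape, macro_centers=(), micro_centers=(), radius_px=10):
    macro = np.zeros(shape, bool)
    micro = np.zeros(shape, bool)
    for (r, c) in macro_centers:
        rr, cc = draw_disk((r, c), radius_px, shape=shape)
        macro[rr, cc] = True
    for (r, c) in micro_centers:
        rr, cc = draw_disk((r, c), radius_px / 2, shape=shape)
        micro[rr, cc] = True
    return SteatosisParams(params={}, macro_mask=macro, micro_mask=micro, region_mask=macro | micro)


def test_collagen_inside_macro_neighborhood_only():
    shape = (128, 128)
    regions = RegionMaskSet.from_tissue(np.ones(shape, bool))
    steat = _steatosis(shape, macro_centers=[(64, 64)])
    collagen_mask = np.zeros(shape, bool)
    collagen_mask[64, 76:82] = True  # just outside the vacuole, within 10 um
    collagen = CollagenMask(collagen_mask, 0, 100 * collagen_mask.mean())
    res = colocalize(collagen, steat, regions, distance_um=10.0, pixel_size_um=PS)
    assert res.coloc_fraction_macro == 1.0
    assert res.coloc_fraction_micro == 0.0


def test_distance_zero_and_disjoint_masks_give_zero_fractions():
    shape = (64, 64)
    regions = RegionMaskSet.from_tissue(np.ones(shape, bool))
    steat = _steatosis(shape, macro_centers=[(16, 16)], micro_centers=[(48, 48)])
    collagen_mask = np.zeros(shape, bool)
    collagen_mask[2, 2:10] = True
    collagen = CollagenMask(collagen_mask, 0, 0.1)
    res = colocalize(collagen, steat, regions, distance_um=0.0, pixel_size_um=PS)
    assert res.coloc_fraction_macro == 0.0 and res.coloc_fraction_micro == 0.0


def test_dimension_mismatch_is_an_error():
    regions = RegionMaskSet.from_tissue(np.ones((32, 32), bool))
    steat = _steatosis((32, 32))
    collagen = CollagenMask(np.zeros((64, 64), bool), 0, 0.0)
    with pytest.raises(Exception):
        colocalize(collagen, steat, regions, 10.0, pixel_size_um=PS)


def _quantify_strings(sample, cfg):
    collagen = segment_collagen(sample.shg, sample.regions.tissue, cfg)
    strings = classify_strings(extract_strings(collagen, sample.regions, PS), cfg, pixel_size_um=PS)
    return collagen, strings


def test_restricted_counts_never_exceed_unrestricted(small_sample, cfg):
    collagen, strings = _quantify_strings(small_sample, cfg)
    full = compute_fibrosis_params(strings, collagen, small_sample.regions)
    from shgquant.steatosis import classify_vacuoles, compute_steatosis_params, detect_vacuole_candidates

    cands = classify_vacuoles(detect_vacuole_candidates(small_sample.tpef, small_sample.regions.tissue))
    steat = compute_steatosis_params(cands, small_sample.regions, cfg.dilation_radius_um, PS)
    res = colocalize(collagen, steat, small_sample.regions, cfg.coloc_distance_um, strings, PS, cfg)
    for params in (res.params_macro, res.params_micro):
        for key in ("#Str", "#LongStrPS", "#ThinStrPS", "#ThinStrPSAgg", "#LongStrPSDis"):
            assert params[key] <= full[key]
    assert (res.collagen_macro & ~collagen.mask).sum() == 0


def test_coloc_counts_monotone_in_distance(small_sample, cfg):
    collagen, strings = _quantify_strings(small_sample, cfg)
    from shgquant.steatosis import classify_vacuoles, compute_steatosis_params, detect_vacuole_candidates

    cands = classify_vacuoles(detect_vacuole_candidates(small_sample.tpef, small_sample.regions.tissue))
    steat = compute_steatosis_params(cands, small_sample.regions, cfg.dilation_radius_um, PS)
    prev = None
    for d in (0.0, 5.0, 10.0, 20.0, 40.0):
        res = colocalize(collagen, steat, small_sample.regions, d, strings, PS, cfg)
        vals = [res.coloc_fraction_macro] + [res.params_macro[k] for k in ("#Str", "#LongStrPS", "#ThinStrPS")]
        if prev is not None:
            assert all(a >= b for a, b in zip(vals, prev))
        prev = vals


def test_full_containment_reproduces_unrestricted_ps_params():
    shape = (128, 128)
    regions = RegionMaskSet.from_tissue(np.ones(shape, bool))
    steat = _steatosis(shape, macro_centers=[(64, 64)], radius_px=40)
    collagen_mask = np.zeros(shape, bool)
    collagen_mask[64, 40:88] = True  # inside the big macro disk -> inside neighborhood
    collagen = CollagenMask(collagen_mask, 0, 100 * collagen_mask.mean())
    strings = classify_strings(extract_strings(collagen, regions, PS), pixel_size_um=PS)
    full = compute_fibrosis_params(strings, collagen, regions)
    res = colocalize(collagen, steat, regions, 10.0, strings, PS)
    for key in ("#Str", "#StrPS", "#LongStrPS", "#ThinStrPS"):
        assert res.params_macro[key] == full[key]


def test_coloc_params_flattening_names():
    shape = (64, 64)
    regions = RegionMaskSet.from_tissue(np.ones(shape, bool))
    steat = _steatosis(shape, macro_centers=[(32, 32)])
    collagen = CollagenMask(np.zeros(shape, bool), 0, 0.0)
    res = colocalize(collagen, steat, regions, 10.0, [], PS)
    flat = coloc_params(res)
    assert flat["#LongStrPS-MacroCoLoc"] == 0.0
    assert flat["#LongStrPS-MicroCoLoc"] == 0.0
    assert flat["ColocFracMacro"] == 0.0
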