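import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from shgquant import (
    AnalysisConfig,
    ChannelImage,
    RegionMaskSet,
    classify_vacuoles,
    compute_steatosis_params,
    detect_vacuole_candidates,
    steatosis_region,
)
from shgquant.steatosis import VacuoleCandidate, default_tree

PS = 0.390625


def _bright_field(shape=(256, 256), value=160):
    return np.full(shape, value, dtype=np.uint8)


def _tpef(pixels):
    return ChannelImage(pixels, PS, "TPEF")


def test_single_dark_disk_detected_with_pixel_oracle():
    img = _bright_field()
    rr, cc = draw_disk((128, 128), 8.0 / PS, shape=img.shape)
    img[rr, cc] = 20
    cands = detect_vacuole_candidates(_tpef(img), np.ones(img.shape, bool))
    assert len(cands) == 1
    stencil_area_um2 = len(rr) * PS**2
    assert abs(cands[0].area_um2 - stencil_area_um2) <= 0.05 * stencil_area_um2
    assert not cands[0].border_touching


def test_uniform_bright_image_has_no_candidates():
    cands = detect_vacuole_candidates(_tpef(_bright_field()), np.ones((256, 256), bool))
    assert cands == []


def test_border_disk_flagged_border_touching():
    img = _bright_field()
    rr, cc = draw_disk((0, 128), 8.0 / PS, shape=img.shape)
    img[rr, cc] = 20
    cands = detect_vacuole_candidates(_tpef(img), np.ones(img.shape, bool))
    assert len(cands) == 1 and cands[0].border_touching


def test_empty_tissue_mask_is_an_error():
    with pytest.raises(ValueError):
        detect_vacuole_candidates(_tpef(_bright_field()), np.zeros((256, 256), bool))


def _cand(diam, circ=0.95, solid=0.9, vessel=False):
    return VacuoleCandidate(
        centroid=(10.0, 10.0), area_um2=np.pi / 4 * diam**2, equiv_diameter_um=diam,
        circularity=circ, solidity=solid, border_touching=False, vessel_overlap=vessel,
        pixels=np.array([[10, 10]]),
    )


@pytest.mark.parametrize(
    "cand,expected",
    [
        (_cand(20.0), "macro"),
        (_cand(4.0), "micro"),
        (_cand(1.5), "rejected"),  # below the micro minimum
        (_cand(20.0, circ=0.2), "rejected"),  # elongated crack
        (_cand(20.0, solid=0.5), "rejected"),
        (_cand(20.0, vessel=True), "rejected"),  # vessel lumen, not fat
    ],
)
def test_default_tree_labels(cand, expected):
    classify_vacuoles([cand])
    assert cand.label == expected


def test_unknown_tree_feature_is_an_error():
    bad = {"feature": "starriness", "threshold": 1, "below": "micro", "above": "macro"}
    with pytest.raises(KeyError, match="starriness"):
        classify_vacuoles([_cand(5.0)], rules=bad)


def test_custom_tree_overrides_default_cut():
    tree = {"feature": "equiv_diameter_um", "threshold": 3.0, "below": "micro", "above": "macro"}
    c = _cand(5.0)
    classify_vacuoles([c], rules=tree)
    assert c.label == "macro"
    assert default_tree(AnalysisConfig())["feature"] == "circularity"


def test_dilation_radius_zero_is_identity_and_negative_errors():
    mask = np.zeros((32, 32), bool)
    mask[10, 10] = True
    assert np.array_equal(steatosis_region(mask, 0.0, PS), mask)
    with pytest.raises(ValueError):
        steatosis_region(mask, -1.0, PS)


def test_dilation_matches_brute_force_distance_oracle():
    rng = np.random.default_rng(3)
    mask = np.zeros((40, 40), bool)
    pts = rng.integers(5, 35, size=(4, 2))
    mask[pts[:, 0], pts[:, 1]] = True
    radius_um = 2.7
    out = steatosis_region(mask, radius_um, PS)
    # brute force: a pixel is inside iff its distance to some foreground
    # pixel is at most the radius
    rr, cc = np.mgrid[0:40, 0:40]
    expect = np.zeros_like(mask)
    for r, c in pts:
        expect |= ((rr - r) ** 2 + (cc - c) ** 2) * PS**2 <= radius_um**2
    assert np.array_equal(out, expect)


def test_dilation_is_monotone_in_radius():
    mask = np.zeros((64, 64), bool)
    mask[30:34, 30:34] = True
    small = steatosis_region(mask, 2.0, PS)
    large = steatosis_region(mask, 5.0, PS)
    assert (small & ~large).sum() == 0


def test_param_arithmetic_and_exact_additivity():
    shape = (64, 64)
    tissue = np.ones(shape, bool)
    regions = RegionMaskSet.from_tissue(tissue)
    macro_px = np.argwhere(np.arange(4096).reshape(shape) < 410)  # ~10% of pixels
    c = VacuoleCandidate(
        centroid=(3.0, 32.0), area_um2=len(macro_px) * PS**2, equiv_diameter_um=12.0,
        circularity=0.9, solidity=0.9, border_touching=False, pixels=macro_px, label="macro",
    )
    params = compute_steatosis_params([c], regions, dilation_radius_um=0.0, pixel_size_um=PS)
    assert params["%Area"] == pytest.approx(100 * 410 / 4096)
    assert params["%MacroArea"] + params["%MicroArea"] == params["%Area"]
    assert params["%MicroArea"] == 0.0
    assert params["#Macro"] == 1


def test_no_candidates_gives_all_zero_params(small_sample):
    params = compute_steatosis_params([], small_sample.regions, 10.0, PS)
    assert all(v == 0.0 for v in params.params.values())


def test_detection_recovery_on_noiseless_sample(small_sample, vacuole_matcher):
    truth, det, pairs = vacuole_matcher(small_sample)
    detectable = [i for i, t in enumerate(truth) if t.diameter_um >= 3.0]
    matched_t = {ti for ti, _ in pairs}
    recall = sum(1 for i in detectable if i in matched_t) / len(detectable)
    precision = len(pairs) / len(det)
    assert recall >= 0.98
    assert precision >= 0.98


def test_classification_recovery_off_boundary(small_sample, vacuole_matcher):
    truth, det, pairs = vacuole_matcher(small_sample)
    assert pairs
    correct = sum(1 for ti, dj in pairs if truth[ti].cls == det[dj].label)
    assert correct / len(pairs) >= 0.98


def test_measured_area_tracks_ground_truth(small_sample, cfg, vacuole_matcher):
    truth_pct = small_sample.truth.true_area_pct
    _, det, _ = vacuole_matcher(small_sample)
    cands = classify_vacuoles(
        detect_vacuole_candidates(
            small_sample.tpef, small_sample.regions.tissue,
            vessel_mask=small_sample.regions.central_vein | small_sample.regions.portal_tract,
        )
    )
    params = compute_steatosis_params(cands, small_sample.regions, cfg.dilation_radius_um, small_sample.pixel_size_um)
    assert abs(params["%Area"] - truth_pct) <= 3.0
    assert params.region_mask[params.macro_mask].all()  # region mask contains vacuoles
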