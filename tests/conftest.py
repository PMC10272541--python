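import numpy as np
import pytest
from scipy.spatial import cKDTree

from shgquant import (
    AnalysisConfig,
    SyntheticSpec,
    generate_sample,
)
from shgquant.steatosis import classify_vacuoles, detect_vacuole_candidates


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sample():
    """One mid-grade, mid-stage noiseless sample on a small canvas."""
    spec = SyntheticSpec(
        target_steatosis_area_pct=12.0,
        macro_fraction=0.7,
        fibrosis_stage=2,
        collagen_coupling=0.6,
        noise_sd=0.0,
        seed=11,
        shape=(256, 256),
    )
    return generate_sample(spec)


@pytest.fixture(scope="session")
def vacuole_matcher():
    """Greedy nearest-centroid matching of detected vacuoles to ground truth."""

    def match(sample, max_dist_um=2.0):
        ps = sample.pixel_size_um
        regions = sample.regions
        vessel = regions.central_vein | regions.portal_tract
        cands = detect_vacuole_candidates(sample.tpef, regions.tissue, vessel_mask=vessel)
        classify_vacuoles(cands)
        det = [c for c in cands if c.label in ("macro", "micro")]
        truth = sample.truth.vacuole_records
        pairs = []
        matched_d = set()
        if det and truth:
            dpts = np.array([c.centroid for c in det]) * ps
            tpts = np.array([t.centroid for t in truth]) * ps
            tree = cKDTree(dpts)
            order = np.argsort([-t.diameter_um for t in truth])
            for ti in order:
                dist, idx = tree.query(tpts[ti], k=min(4, len(det)), distance_upper_bound=max_dist_um)
                for dd, dj in zip(np.atleast_1d(dist), np.atleast_1d(idx)):
                    if np.isfinite(dd) and dj not in matched_d:
                        matched_d.add(int(dj))
                        pairs.append((int(ti), int(dj)))
                        break
        return truth, det, pairs

    return match
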