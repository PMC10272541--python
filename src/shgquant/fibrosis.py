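"""Collagen segmentation and string morphometry in the SHG channel.

Collagen is separated from background by Otsu thresholding of the
tissue-restricted intensity histogram.  Each 8-connected component is a
"string"; its geodesic skeleton length, mean width (area / length), lobular
region and branch points feed the named fibrosis parameters, among them the
four perisinusoidal string counts (#LongStrPS, #ThinStrPS, #ThinStrPSAgg,
#LongStrPSDis) and the collagen proportionate area (CPA) analog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .config import AnalysisConfig
from .io_core import ChannelImage, RegionMaskSet

_SQRT2 = float(np.sqrt(2.0))


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


def otsu_threshold(histogram: Sequence[float]) -> int:
    """Between-class-variance maximizing threshold of an intensity histogram.

    Parameters
    ----------
    histogram : sequence of counts
        ``histogram[i]`` is the number of pixels with intensity ``i``.

    Returns
    -------
    int
        Threshold ``t``; the foreground class is strictly greater than
        ``t``.  Ties are broken toward the smallest maximizing ``t``.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be one-dimensional")
    if int((hist > 0).sum()) < 2:
        raise DegenerateHistogramError("histogram has < 2 non-empty bins")
    p = hist / hist.sum()
    levels = np.arange(hist.size, dtype=float)
    w0 = np.cumsum(p)[:-1]
    m0 = np.cumsum(p * levels)[:-1]
    mu_total = float(np.sum(p * levels))
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * w1)
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def bimodal_threshold(values: np.ndarray, separation_fraction: float = 0.33, min_z: float = 6.0):
    """Otsu threshold of an integer-valued sample, with a bimodality guard.

    Returns ``(threshold, ok)``.  ``ok`` is ``False`` when the histogram is
    degenerate (single occupied bin) or the two Otsu classes are not truly
    separated — the near-unimodal case in which any split is noise.  Two
    criteria must hold: the class means differ by at least
    ``separation_fraction`` of the upper mean, and by at least ``min_z``
    pooled within-class standard deviations (an Otsu split of a unimodal
    Gaussian separates its halves by only ~2.7 such deviations).
    """
    values = np.asarray(values)
    ivals = np.rint(values).astype(np.int64)
    ivals = np.clip(ivals, 0, None)
    hist = np.bincount(ivals.ravel())
    if int((hist > 0).sum()) < 2:
        return 0, False
    t = otsu_threshold(hist)
    lo = ivals[ivals <= t]
    hi = ivals[ivals > t]
    mu_lo, mu_hi = float(lo.mean()), float(hi.mean())
    sep = mu_hi - mu_lo
    w_lo = len(lo) / len(ivals)
    sigma_w = float(np.sqrt(w_lo * lo.var() + (1 - w_lo) * hi.var()))
    ok = sep >= separation_fraction * max(mu_hi, 1.0) and (sigma_w == 0 or sep >= min_z * sigma_w)
    return t, ok


@dataclass
class CollagenMask:
    """Thresholded collagen signal within the tissue mask."""

    mask: np.ndarray
    threshold: float
    area_pct: float  # percent of tissue area; this is the CPA analog
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class CollagenString:
    """One connected collagen component with skeleton-derived morphology."""

    component_id: int
    skeleton: np.ndarray  # (n, 2) array of skeleton pixel coordinates
    centroid: tuple[float, float]
    area_um2: float
    length_um: float
    mean_width_um: float
    region: str  # "CV" | "PT" | "PS"
    n_branch_points: int
    pixels: np.ndarray = field(repr=False, default=None)  # (n, 2) component pixels
    is_long: Optional[bool] = None
    is_thin: Optional[bool] = None
    is_aggregated: Optional[bool] = None
    is_distributed: Optional[bool] = None


def segment_collagen(
    shg: ChannelImage,
    tissue: np.ndarray,
    config: Optional[AnalysisConfig] = None,
) -> CollagenMask:
    """Segment collagen from the SHG channel inside the tissue mask.

    The Otsu threshold is computed on the tissue-restricted histogram;
    components smaller than ``min_collagen_area_um2`` are removed.  A
    degenerate (near-signal-free) histogram yields an empty mask with a
    warning rather than an error, since stage-0 samples can be almost free
    of collagen.
    """
    config = config or AnalysisConfig()
    tissue = np.asarray(tissue, dtype=bool)
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    values = np.asarray(shg.pixels)[tissue]
    threshold, ok = bimodal_threshold(values)
    if not ok:
        warnings.warn("degenerate SHG histogram; returning empty collagen mask", stacklevel=2)
        empty = np.zeros_like(tissue)
        return CollagenMask(mask=empty, threshold=float(threshold), area_pct=0.0, degenerate=True)
    mask = (np.asarray(shg.pixels) > threshold) & tissue
    min_px = max(int(round(config.min_collagen_area_um2 / shg.pixel_size_um**2)), 1)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_px
        keep[0] = False
        mask = keep[labels]
    area_pct = 100.0 * mask.sum() / tissue.sum()
    return CollagenMask(mask=mask, threshold=float(threshold), area_pct=float(area_pct))


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_length_px(skel: np.ndarray) -> tuple[float, int]:
    """Geodesic length (pixel units) and branch-point count of a skeleton mask.

    Length is the sum of step lengths (1 for orthogonal, sqrt(2) for
    diagonal) over unique adjacent skeleton-pixel pairs; a diagonal step is
    skipped when the two pixels share a common orthogonal skeleton neighbor
    (it would double-count the corner).  Branch points are skeleton pixels
    with three or more skeleton neighbors.
    """
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return 0.0, 0
    pix = {tuple(c) for c in coords}
    length = 0.0
    n_branch = 0
    for r, c in pix:
        deg = 0
        for dr, dc in _NEIGHBOR_OFFSETS:
            q = (r + dr, c + dc)
            if q not in pix:
                continue
            deg += 1
            if q <= (r, c):
                continue  # count each unordered pair once
            if dr and dc:
                # skip diagonal edges closing a right-angle triangle
                if (r, c + dc) in pix or (r + dr, c) in pix:
                    continue
                length += _SQRT2
            else:
                length += 1.0
        if deg >= 3:
            n_branch += 1
    return length, n_branch


def _majority_region(coords: np.ndarray, regions: RegionMaskSet) -> str:
    rr, cc = coords[:, 0], coords[:, 1]
    votes = {
        "CV": int(regions.central_vein[rr, cc].sum()),
        "PT": int(regions.portal_tract[rr, cc].sum()),
        "PS": int(regions.perisinusoidal[rr, cc].sum()),
    }
    return max(votes, key=lambda k: (votes[k], k == "PS"))


def extract_strings(
    collagen: CollagenMask,
    regions: RegionMaskSet,
    pixel_size_um: float,
    exclude_mask: Optional[np.ndarray] = None,
) -> list[CollagenString]:
    """Decompose the collagen mask into strings with morphology attributes.

    ``exclude_mask`` drops strings lying entirely inside it (e.g. vessel
    lumens, whose wall collagen is physiologic).  An empty collagen mask
    yields an empty list.
    """
    labels, n = ndi.label(collagen.mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    skel_all = skeletonize(collagen.mask)
    strings: list[CollagenString] = []
    objects = ndi.find_objects(labels)
    for cid in range(1, n + 1):
        sl = objects[cid - 1]
        comp = labels[sl] == cid
        coords = np.argwhere(comp)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        if exclude_mask is not None and exclude_mask[coords[:, 0], coords[:, 1]].all():
            continue
        skel = skel_all[sl] & comp
        length_px, n_branch = _skeleton_length_px(skel)
        length_px = max(length_px, 1.0)  # a point-like component spans at least one pixel
        area_px = len(coords)
        length_um = length_px * pixel_size_um
        mean_width_um = area_px * pixel_size_um**2 / length_um
        skel_coords = np.argwhere(skel)
        if len(skel_coords):
            skel_coords = skel_coords + np.array([sl[0].start, sl[1].start])
        strings.append(
            CollagenString(
                component_id=cid,
                skeleton=skel_coords,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                area_um2=area_px * pixel_size_um**2,
                length_um=float(length_um),
                mean_width_um=float(mean_width_um),
                region=_majority_region(coords, regions),
                n_branch_points=int(n_branch),
                pixels=coords,
            )
        )
    return strings


def classify_strings(
    strings: list[CollagenString],
    config: Optional[AnalysisConfig] = None,
    pixel_size_um: float = 1.0,
) -> list[CollagenString]:
    """Set the long/thin and aggregated/distributed flags on each string.

    A string is aggregated when at least ``agg_min_neighbors`` other string
    centroids lie within ``agg_radius_um``; otherwise it is distributed.
    Flags are set in place; the list is returned for chaining.
    """
    config = config or AnalysisConfig()
    if config.long_min_um <= 0 or config.thin_max_um <= 0 or config.agg_radius_um < 0:
        raise ValueError("string classification thresholds must be positive")
    if not strings:
        return strings
    centroids = np.array([s.centroid for s in strings], dtype=float) * pixel_size_um
    tree = cKDTree(centroids)
    counts = tree.query_ball_point(centroids, r=config.agg_radius_um, return_length=True)
    for s, n_in_ball in zip(strings, counts):
        s.is_long = s.length_um >= config.long_min_um
        s.is_thin = s.mean_width_um <= config.thin_max_um
        s.is_aggregated = (int(n_in_ball) - 1) >= config.agg_min_neighbors
        s.is_distributed = not s.is_aggregated
    return strings


#: Parameter names emitted by :func:`compute_fibrosis_params`.
FIBROSIS_PARAM_NAMES = (
    "CPA", "#Str", "#StrCV", "#StrPT", "#StrPS",
    "#LongStrPS", "#ThinStrPS", "#ThinStrPSAgg", "#LongStrPSDis",
    "TotalLengthPS", "MeanWidthPS", "#BranchPoints",
)


def compute_fibrosis_params(
    strings: list[CollagenString],
    collagen: CollagenMask,
    regions: Optional[RegionMaskSet] = None,
) -> dict[str, float]:
    """Aggregate flagged strings into the named fibrosis parameter map."""
    for s in strings:
        if s.is_long is None:
            raise ValueError("strings must be classified before computing parameters")
    ps = [s for s in strings if s.region == "PS"]
    params = {
        "CPA": float(collagen.area_pct),
        "#Str": float(len(strings)),
        "#StrCV": float(sum(s.region == "CV" for s in strings)),
        "#StrPT": float(sum(s.region == "PT" for s in strings)),
        "#StrPS": float(len(ps)),
        "#LongStrPS": float(sum(s.is_long for s in ps)),
        "#ThinStrPS": float(sum(s.is_thin for s in ps)),
        "#ThinStrPSAgg": float(sum(s.is_thin and s.is_aggregated for s in ps)),
        "#LongStrPSDis": float(sum(s.is_long and s.is_distributed for s in ps)),
        "TotalLengthPS": float(sum(s.length_um for s in ps)),
        "MeanWidthPS": float(np.mean([s.mean_width_um for s in ps])) if ps else 0.0,
        "#BranchPoints": float(sum(s.n_branch_points for s in strings)),
    }
    return params
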