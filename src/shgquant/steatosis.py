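"""Fat-vacuole detection, macro/micro classification and steatosis parameters.

Vacuole candidates are the dark ("black hole") connected components of the
TPEF channel inside tissue.  Each candidate is labeled macro, micro, or
rejected by a binary decision tree over its shape features; the default
tree rejects low-circularity / low-solidity components (cracks, sinusoids)
and cuts macro from micro at an equivalent diameter of 10 um.  Steatosis
regions are the morphological dilation of the vacuole mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label, regionprops

from .config import AnalysisConfig
from .fibrosis import bimodal_threshold
from .io_core import ChannelImage, RegionMaskSet


@dataclass
class VacuoleCandidate:
    """One dark connected component with shape features."""

    centroid: tuple[float, float]  # (row, col)
    area_um2: float
    equiv_diameter_um: float
    circularity: float  # 4*pi*area / perimeter**2, clipped to [0, 1.05]
    solidity: float
    border_touching: bool
    vessel_overlap: bool = False
    collagen_density: float = 0.0  # collagen area fraction within 5 um of the boundary
    label: str = "unlabeled"  # macro | micro | rejected | unlabeled
    pixels: np.ndarray = field(repr=False, default=None)  # (n, 2) pixel coordinates


def dark_threshold(
    tpef: ChannelImage,
    tissue: np.ndarray,
    config: Optional[AnalysisConfig] = None,
) -> float:
    """Intensity below-or-equal which a tissue pixel counts as dark.

    Otsu on the tissue-restricted histogram (lower class) when the
    histogram is bimodal; otherwise a fixed fraction of the tissue median —
    the symmetric counterpart of the collagen thresholding rule.
    """
    config = config or AnalysisConfig()
    values = np.asarray(tpef.pixels)[tissue]
    if config.dark_threshold_mode == "otsu":
        t, ok = bimodal_threshold(values)
        if ok:
            return float(t)
    return float(config.dark_fixed_fraction * np.median(values))


def _fill_small_holes(mask: np.ndarray, max_hole_px: int) -> np.ndarray:
    """Fill enclosed background pockets smaller than ``max_hole_px``.

    Unlike a blanket hole fill, large bright pockets between tightly packed
    vacuoles are preserved, so neighbours are not merged into one component.
    """
    if max_hole_px < 1:
        return mask
    bg = ~mask
    labels, n = ndi.label(bg)  # 4-connectivity for the complement of an 8-connected mask
    if n == 0:
        return mask
    border_labels = np.unique(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
    sizes = np.bincount(labels.ravel())
    fill = (sizes <= max_hole_px)
    fill[border_labels] = False
    fill[0] = False
    return mask | fill[labels]


def detect_vacuole_candidates(
    tpef: ChannelImage,
    tissue: np.ndarray,
    vessel_mask: Optional[np.ndarray] = None,
    collagen_mask: Optional[np.ndarray] = None,
    config: Optional[AnalysisConfig] = None,
) -> list[VacuoleCandidate]:
    """Detect dark-hole vacuole candidates in the TPEF channel.

    Candidates are connected dark components strictly inside tissue, with
    small enclosed holes filled, of area >= ``min_vacuole_area_um2``.
    Components touching the image border are flagged ``border_touching``
    (they are excluded from area parameters downstream); components
    overlapping ``vessel_mask`` are flagged for rejection.  When a
    ``collagen_mask`` is provided, the collagen density within 5 um of each
    candidate boundary is recorded as an additional classification feature.
    """
    config = config or AnalysisConfig()
    tissue = np.asarray(tissue, dtype=bool)
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    ps = tpef.pixel_size_um
    thr = dark_threshold(tpef, tissue, config)
    dark = (np.asarray(tpef.pixels, dtype=float) <= thr) & tissue
    dark = _fill_small_holes(dark, int(round(config.fill_hole_max_um2 / ps**2)))
    labels = sk_label(dark, connectivity=2)
    min_area_px = config.min_vacuole_area_um2 / ps**2
    nrows, ncols = dark.shape
    out: list[VacuoleCandidate] = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        border = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        perim = max(float(prop.perimeter_crofton), 1.0)
        circularity = min(4.0 * np.pi * prop.area / perim**2, 1.05)
        coords = prop.coords
        vessel = False
        if vessel_mask is not None:
            vessel = bool(vessel_mask[coords[:, 0], coords[:, 1]].any())
        collagen_density = 0.0
        if collagen_mask is not None:
            pad = int(np.ceil(5.0 / ps))
            rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
            rr1, cc1 = min(r1 + pad, nrows), min(c1 + pad, ncols)
            sub = labels[rr0:rr1, cc0:cc1] == prop.label
            ring = (ndi.distance_transform_edt(~sub) * ps <= 5.0) & ~sub
            n_ring = ring.sum()
            if n_ring:
                collagen_density = float(collagen_mask[rr0:rr1, cc0:cc1][ring].sum() / n_ring)
        out.append(
            VacuoleCandidate(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_um2=float(prop.area * ps**2),
                equiv_diameter_um=float(prop.equivalent_diameter_area * ps),
                circularity=float(circularity),
                solidity=float(prop.solidity),
                border_touching=border,
                vessel_overlap=vessel,
                collagen_density=collagen_density,
                pixels=coords,
            )
        )
    return out


def default_tree(config: Optional[AnalysisConfig] = None) -> dict:
    """Default macro/micro decision tree over shape features.

    Nodes are ``{"feature", "threshold", "below", "above"}`` dictionaries
    (``below``: feature < threshold); leaves are label strings.  A trained
    tree in the same form can be loaded from config to replace it.
    """
    config = config or AnalysisConfig()
    return {
        "feature": "circularity",
        "threshold": config.min_circularity,
        "below": "rejected",
        "above": {
            "feature": "solidity",
            "threshold": config.min_solidity,
            "below": "rejected",
            "above": {
                "feature": "equiv_diameter_um",
                "threshold": config.micro_min_diameter_um,
                "below": "rejected",
                "above": {
                    "feature": "equiv_diameter_um",
                    "threshold": config.macro_min_diameter_um,
                    "below": "micro",
                    "above": "macro",
                },
            },
        },
    }


_TREE_FEATURES = ("equiv_diameter_um", "circularity", "solidity", "area_um2", "collagen_density")


def _eval_tree(node, cand: VacuoleCandidate) -> str:
    while not isinstance(node, str):
        feat = node["feature"]
        if feat not in _TREE_FEATURES:
            raise KeyError(f"unknown feature {feat!r} in decision tree; known: {_TREE_FEATURES}")
        value = getattr(cand, feat)
        node = node["below"] if value < node["threshold"] else node["above"]
    if node not in ("macro", "micro", "rejected"):
        raise ValueError(f"unknown leaf label {node!r}")
    return node


def classify_vacuoles(
    candidates: list[VacuoleCandidate],
    rules: Optional[dict] = None,
    config: Optional[AnalysisConfig] = None,
) -> list[VacuoleCandidate]:
    """Label each candidate macro, micro, or rejected.

    Candidates overlapping vessel lumens are rejected outright (vessel
    lumens are dark holes but not fat).  Labels are set in place.
    """
    tree = rules if rules is not None else default_tree(config)
    for cand in candidates:
        cand.label = "rejected" if cand.vessel_overlap else _eval_tree(tree, cand)
    return candidates


def steatosis_region(
    vacuole_mask: np.ndarray,
    dilation_radius_um: float,
    pixel_size_um: float,
    tissue: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Dilate the vacuole mask by a physical radius (disk structuring element).

    Implemented as a Euclidean distance-transform threshold, which is exact
    for non-integer pixel radii.  Radius 0 returns the input; the result is
    intersected with the tissue mask when one is given.
    """
    if dilation_radius_um < 0:
        raise ValueError(f"dilation radius must be non-negative, got {dilation_radius_um}")
    vacuole_mask = np.asarray(vacuole_mask, dtype=bool)
    if dilation_radius_um == 0:
        out = vacuole_mask.copy()
    elif not vacuole_mask.any():
        out = vacuole_mask.copy()
    else:
        dt = ndi.distance_transform_edt(~vacuole_mask) * pixel_size_um
        out = dt <= dilation_radius_um
    if tissue is not None:
        out &= np.asarray(tissue, dtype=bool)
    return out


@dataclass
class SteatosisParams:
    """Named steatosis parameters plus the masks downstream stages consume."""

    params: dict[str, float]
    macro_mask: np.ndarray
    micro_mask: np.ndarray
    region_mask: np.ndarray  # dilated steatosis region

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _pct(mask: np.ndarray, region: np.ndarray) -> float:
    denom = int(region.sum())
    if denom == 0:
        return 0.0
    return 100.0 * int((mask & region).sum()) / denom


def compute_steatosis_params(
    candidates: list[VacuoleCandidate],
    regions: RegionMaskSet,
    dilation_radius_um: float,
    pixel_size_um: float,
) -> SteatosisParams:
    """Compute the named steatosis parameter map from classified candidates.

    Percentages are vacuole pixels over region pixels; border-touching
    candidates are excluded from all area parameters and counts.
    %MacroArea + %MicroArea = %Area holds exactly because macro and micro
    masks partition the counted vacuole pixels.
    """
    if not regions.tissue.any():
        raise ValueError("tissue mask is empty")
    for cand in candidates:
        if cand.label == "unlabeled":
            raise ValueError("candidates must be classified first")
    shape = regions.tissue.shape
    macro_mask = np.zeros(shape, dtype=bool)
    micro_mask = np.zeros(shape, dtype=bool)
    macro_diams, micro_diams = [], []
    n_macro = n_micro = 0
    for cand in candidates:
        if cand.border_touching or cand.label not in ("macro", "micro"):
            continue
        target = macro_mask if cand.label == "macro" else micro_mask
        target[cand.pixels[:, 0], cand.pixels[:, 1]] = True
        if cand.label == "macro":
            n_macro += 1
            macro_diams.append(cand.equiv_diameter_um)
        else:
            n_micro += 1
            micro_diams.append(cand.equiv_diameter_um)
    macro_mask &= regions.tissue
    micro_mask &= regions.tissue
    vac = macro_mask | micro_mask
    region_mask = steatosis_region(vac, dilation_radius_um, pixel_size_um, regions.tissue)
    params: dict[str, float] = {}
    for suffix, region in (
        ("", regions.tissue),
        ("CV", regions.central_vein),
        ("PT", regions.portal_tract),
        ("PS", regions.perisinusoidal),
    ):
        params[f"%MacroArea{suffix}"] = _pct(macro_mask, region)
        params[f"%MicroArea{suffix}"] = _pct(micro_mask, region)
        params[f"%Area{suffix}"] = params[f"%MacroArea{suffix}"] + params[f"%MicroArea{suffix}"]
    params["#Macro"] = float(n_macro)
    params["#Micro"] = float(n_micro)
    params["MacroDiam"] = float(np.mean(macro_diams)) if macro_diams else 0.0
    params["MicroDiam"] = float(np.mean(micro_diams)) if micro_diams else 0.0
    params["%SteatosisRegion"] = _pct(region_mask, regions.tissue)
    return SteatosisParams(params=params, macro_mask=macro_mask, micro_mask=micro_mask, region_mask=region_mask)


#: Parameter names emitted by :func:`compute_steatosis_params`.
STEATOSIS_PARAM_NAMES = (
    "%Area", "%MacroArea", "%MicroArea",
    "%AreaCV", "%MacroAreaCV", "%MicroAreaCV",
    "%AreaPT", "%MacroAreaPT", "%MicroAreaPT",
    "%AreaPS", "%MacroAreaPS", "%MicroAreaPS",
    "#Macro", "#Micro", "MacroDiam", "MicroDiam", "%SteatosisRegion",
)
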