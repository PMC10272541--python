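"""Fibrosis restricted to the neighbourhood of each steatosis class.

The neighbourhood of a steatosis class is the vacuole mask of that class
dilated by a fixed physical distance and intersected with the
perisinusoidal region.  Area fractions use pixel-level intersection;
string-count parameters use whole-string attribution (a string counts when
at least half of its pixels fall inside the neighbourhood), since counts
need whole-object semantics while areas need measure semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .config import AnalysisConfig
from .fibrosis import CollagenMask, CollagenString, compute_fibrosis_params
from .io_core import DimensionMismatchError, RegionMaskSet
from .steatosis import SteatosisParams


@dataclass
class ColocalizationResult:
    macro_neighborhood: np.ndarray
    micro_neighborhood: np.ndarray
    collagen_macro: np.ndarray
    collagen_micro: np.ndarray
    coloc_fraction_macro: float
    coloc_fraction_micro: float
    params_macro: dict[str, float]
    params_micro: dict[str, float]


def _neighborhood(class_mask: np.ndarray, ps_region: np.ndarray, distance_um: float, pixel_size_um: float) -> np.ndarray:
    if not class_mask.any():
        return np.zeros_like(class_mask)
    if distance_um == 0:
        return class_mask & ps_region
    dt = ndi.distance_transform_edt(~class_mask) * pixel_size_um
    return (dt <= distance_um) & ps_region


def _restrict(
    strings: list[CollagenString],
    neighborhood: np.ndarray,
    attribution: str,
) -> list[CollagenString]:
    kept = []
    for s in strings:
        inside = neighborhood[s.pixels[:, 0], s.pixels[:, 1]]
        frac = inside.mean() if len(inside) else 0.0
        if attribution == "whole":
            if frac >= 0.5:
                kept.append(s)
        else:  # "clip": keep strings with any overlap, counted once
            if frac > 0:
                kept.append(s)
    return kept


def colocalize(
    collagen: CollagenMask,
    steatosis: SteatosisParams,
    regions: RegionMaskSet,
    distance_um: float,
    strings: Optional[list[CollagenString]] = None,
    pixel_size_um: float = 1.0,
    config: Optional[AnalysisConfig] = None,
) -> ColocalizationResult:
    """Restrict collagen to the macro- and micro-steatosis neighbourhoods.

    String flags are *not* recomputed on the restricted subset, so every
    co-localized count is bounded above by its unrestricted counterpart.
    """
    config = config or AnalysisConfig()
    if distance_um < 0:
        raise ValueError("distance_um must be non-negative")
    if collagen.mask.shape != steatosis.macro_mask.shape or collagen.mask.shape != regions.tissue.shape:
        raise DimensionMismatchError(
            f"mask shapes differ: collagen {collagen.mask.shape}, "
            f"steatosis {steatosis.macro_mask.shape}, regions {regions.tissue.shape}"
        )
    strings = strings or []
    ps_region = regions.perisinusoidal
    total_collagen = int(collagen.mask.sum())
    tissue_px = int(regions.tissue.sum())
    out = {}
    for cls, class_mask in (("macro", steatosis.macro_mask), ("micro", steatosis.micro_mask)):
        nb = _neighborhood(class_mask, ps_region, distance_um, pixel_size_um)
        coll = collagen.mask & nb
        frac = coll.sum() / total_collagen if total_collagen else 0.0
        kept = _restrict(strings, nb, config.coloc_attribution)
        sub_mask = CollagenMask(
            mask=coll,
            threshold=collagen.threshold,
            area_pct=100.0 * coll.sum() / tissue_px if tissue_px else 0.0,
            degenerate=collagen.degenerate,
        )
        out[cls] = (nb, coll, float(frac), compute_fibrosis_params(kept, sub_mask, regions))
    return ColocalizationResult(
        macro_neighborhood=out["macro"][0],
        micro_neighborhood=out["micro"][0],
        collagen_macro=out["macro"][1],
        collagen_micro=out["micro"][1],
        coloc_fraction_macro=out["macro"][2],
        coloc_fraction_micro=out["micro"][2],
        params_macro=out["macro"][3],
        params_micro=out["micro"][3],
    )


def coloc_params(result: ColocalizationResult) -> dict[str, float]:
    """Flatten a co-localization result into suffixed parameter names.

    ``#LongStrPS`` restricted to the macrosteatosis neighbourhood becomes
    ``#LongStrPS-MacroCoLoc`` and so on, mirroring the
    qFibrosis-MacroCoLocalization / -MicroCoLocalization report columns.
    """
    flat: dict[str, float] = {}
    for suffix, params in (("-MacroCoLoc", result.params_macro), ("-MicroCoLoc", result.params_micro)):
        for name, value in params.items():
            flat[f"{name}{suffix}"] = value
    flat["ColocFracMacro"] = result.coloc_fraction_macro
    flat["ColocFracMicro"] = result.coloc_fraction_micro
    return flat
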