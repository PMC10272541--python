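"""Image/table I/O and the spatial conventions shared by every analysis stage.

Conventions
-----------
* Pixel grid with origin at the top-left corner, ``(row, col)`` indexing.
* Binary masks are boolean arrays with ``True`` = foreground.
* Physical areas are pixel counts scaled by ``pixel_size_um ** 2``; lengths
  are scaled by ``pixel_size_um``.
* A tile acquired at 20x covers 200 x 200 um^2 at 512 x 512 px, giving the
  default pixel pitch of 200/512 = 0.390625 um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

#: Physical pixel pitch (um) of a 512 px tile spanning 200 um.
DEFAULT_PIXEL_SIZE_UM = 200.0 / 512.0

CHANNELS = ("SHG", "TPEF")

#: Label values used in region label images.
REGION_LABELS = {"background": 0, "central_vein": 1, "portal_tract": 2, "perisinusoidal": 3}


class DimensionMismatchError(ValueError):
    """Paired images or masks do not share a pixel grid."""


@dataclass
class ChannelImage:
    """A single-channel intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative intensity grid.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    channel : str
        Either ``"SHG"`` (collagen) or ``"TPEF"`` (autofluorescence).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "TPEF"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.nanmin(self.pixels) < 0:
            raise ValueError("intensity values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class RegionMaskSet:
    """Binary masks for the lobular regions of one sample.

    ``central_vein``, ``portal_tract`` and ``perisinusoidal`` are pairwise
    disjoint and their union equals ``tissue``.
    """

    tissue: np.ndarray
    central_vein: np.ndarray
    portal_tract: np.ndarray
    perisinusoidal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tissue", "central_vein", "portal_tract", "perisinusoidal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.validate()

    def validate(self) -> None:
        shapes = {m.shape for m in (self.tissue, self.central_vein, self.portal_tract, self.perisinusoidal)}
        if len(shapes) != 1:
            raise DimensionMismatchError(f"region masks have mismatched shapes: {sorted(shapes)}")
        if np.any(self.central_vein & self.portal_tract) or np.any(self.central_vein & self.perisinusoidal) or np.any(self.portal_tract & self.perisinusoidal):
            raise ValueError("region masks must be pairwise disjoint")
        union = self.central_vein | self.portal_tract | self.perisinusoidal
        if not np.array_equal(union, self.tissue):
            raise ValueError("union of region masks must equal the tissue mask")

    @classmethod
    def from_tissue(cls, tissue: np.ndarray) -> "RegionMaskSet":
        """Treat the whole tissue as perisinusoidal (no annotation available)."""
        tissue = np.asarray(tissue, dtype=bool)
        empty = np.zeros_like(tissue)
        return cls(tissue=tissue, central_vein=empty.copy(), portal_tract=empty.copy(), perisinusoidal=tissue.copy())

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "RegionMaskSet":
        labels = np.asarray(labels)
        cv = labels == REGION_LABELS["central_vein"]
        pt = labels == REGION_LABELS["portal_tract"]
        ps = labels == REGION_LABELS["perisinusoidal"]
        return cls(tissue=cv | pt | ps, central_vein=cv, portal_tract=pt, perisinusoidal=ps)

    def to_labels(self) -> np.ndarray:
        labels = np.zeros(self.tissue.shape, dtype=np.uint8)
        labels[self.central_vein] = REGION_LABELS["central_vein"]
        labels[self.portal_tract] = REGION_LABELS["portal_tract"]
        labels[self.perisinusoidal] = REGION_LABELS["perisinusoidal"]
        return labels


@dataclass
class TissueSample:
    """Paired SHG/TPEF images with region masks and metadata."""

    shg: ChannelImage
    tpef: ChannelImage
    regions: RegionMaskSet
    sample_id: str = "sample"
    group: str = ""
    week: int = 0
    truth: Optional[object] = None  # GroundTruth for synthetic samples

    def __post_init__(self) -> None:
        if self.shg.shape != self.tpef.shape:
            raise DimensionMismatchError(
                f"SHG shape {self.shg.shape} != TPEF shape {self.tpef.shape}"
            )
        if self.shg.pixel_size_um != self.tpef.pixel_size_um:
            raise ValueError("SHG and TPEF pixel sizes differ")
        if self.regions.tissue.shape != self.shg.shape:
            raise DimensionMismatchError(
                f"region mask shape {self.regions.tissue.shape} != image shape {self.shg.shape}"
            )

    @property
    def pixel_size_um(self) -> float:
        return self.shg.pixel_size_um


def derive_tissue_mask(
    tpef_pixels: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    intensity_fraction: float = 0.05,
    min_component_um2: float = 1000.0,
) -> np.ndarray:
    """Estimate the tissue footprint from TPEF autofluorescence.

    Pixels brighter than ``intensity_fraction`` of the channel's 99th
    percentile are kept, holes are filled and components smaller than
    ``min_component_um2`` are dropped.
    """
    px = np.asarray(tpef_pixels, dtype=float)
    ref = np.percentile(px, 99)
    mask = px > intensity_fraction * ref
    mask = ndi.binary_fill_holes(mask)
    min_px = int(round(min_component_um2 / pixel_size_um**2))
    labels, n = ndi.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= max(min_px, 1)
        keep[0] = False
        mask = keep[labels]
    return mask


def _read_gray(path: Path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(arr)


def read_sample(
    shg_path,
    tpef_path=None,
    regions_path=None,
    meta: Optional[Mapping] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> TissueSample:
    """Read a paired sample from disk.

    Accepts either two single-plane grayscale TIFFs, or one two-page TIFF
    (SHG first) with ``tpef_path=None``.  When no region label image is
    given, the tissue mask is derived from TPEF and the whole tissue is
    treated as perisinusoidal.
    """
    meta = dict(meta or {})
    shg_arr = _read_gray(shg_path)
    if tpef_path is None:
        if shg_arr.ndim != 3 or shg_arr.shape[0] != 2:
            raise ValueError(
                f"single-file input must be a two-page TIFF (SHG first), got shape {shg_arr.shape}"
            )
        shg_arr, tpef_arr = shg_arr[0], shg_arr[1]
    else:
        tpef_arr = _read_gray(tpef_path)
    if shg_arr.ndim != 2 or tpef_arr.ndim != 2:
        raise ValueError("channel images must be single-plane grayscale")
    if shg_arr.shape != tpef_arr.shape:
        raise DimensionMismatchError(f"SHG shape {shg_arr.shape} != TPEF shape {tpef_arr.shape}")

    if regions_path is not None:
        labels = _read_gray(regions_path)
        if labels.shape != shg_arr.shape:
            raise DimensionMismatchError(
                f"region label shape {labels.shape} != image shape {shg_arr.shape}"
            )
        regions = RegionMaskSet.from_labels(labels)
    else:
        tissue = derive_tissue_mask(tpef_arr, pixel_size_um)
        regions = RegionMaskSet.from_tissue(tissue)

    return TissueSample(
        shg=ChannelImage(shg_arr, pixel_size_um, "SHG"),
        tpef=ChannelImage(tpef_arr, pixel_size_um, "TPEF"),
        regions=regions,
        sample_id=str(meta.get("sample_id", Path(shg_path).stem)),
        group=str(meta.get("group", "")),
        week=int(meta.get("week", 0)),
    )


def write_sample(sample: TissueSample, out_dir) -> dict:
    """Write a sample as ``shg.tif``, ``tpef.tif``, ``regions.tif``, ``meta.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "shg": out_dir / "shg.tif",
        "tpef": out_dir / "tpef.tif",
        "regions": out_dir / "regions.tif",
        "meta": out_dir / "meta.json",
    }
    tifffile.imwrite(paths["shg"], sample.shg.pixels)
    tifffile.imwrite(paths["tpef"], sample.tpef.pixels)
    tifffile.imwrite(paths["regions"], sample.regions.to_labels())
    meta = {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "week": sample.week,
        "pixel_size_um": sample.pixel_size_um,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def stitch_tiles(tiles: Sequence[Sequence[ChannelImage]]) -> ChannelImage:
    """Assemble a rectangular grid of equal tiles into one mosaic.

    ``tiles[i][j]`` is placed with its top-left corner at
    ``(i * H, j * W)``.  All tiles must share shape, channel and pixel size.
    """
    if not tiles or not tiles[0]:
        raise ValueError("tile grid is empty")
    ncols = len(tiles[0])
    if any(len(row) != ncols for row in tiles):
        raise ValueError("tile grid is ragged")
    first = tiles[0][0]
    for row in tiles:
        for t in row:
            if t.shape != first.shape:
                raise ValueError(f"tile shape {t.shape} != {first.shape}")
            if t.channel != first.channel:
                raise ValueError("mixed channels in tile grid")
            if t.pixel_size_um != first.pixel_size_um:
                raise ValueError("mixed pixel sizes in tile grid")
    mosaic = np.block([[t.pixels for t in row] for row in tiles])
    return ChannelImage(mosaic, first.pixel_size_um, first.channel)


#: Metadata columns that accompany parameter columns in a parameter table.
TABLE_META_COLUMNS = ("sample_id", "group", "week", "grade", "stage")


def write_param_table(table: pd.DataFrame, path) -> None:
    """Write a per-sample parameter table to CSV (12 significant digits)."""
    if len(table) == 0:
        raise ValueError("parameter table is empty")
    if "sample_id" not in table.columns:
        raise ValueError("parameter table must contain a sample_id column")
    dup = table["sample_id"][table["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
    table.to_csv(path, index=False, float_format="%.12g")


def read_param_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    dup = table["sample_id"][table["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
    return table
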