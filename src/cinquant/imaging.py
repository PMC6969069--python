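"""Nuclear segmentation, cell-body masks and micronucleus detection.

The mask-and-filter scheme mirrors automated single-cell quantitative
imaging of Hoechst-stained fields:

1. a *primary* (nuclear) mask — global Otsu threshold, hole filling, and
   distance-transform watershed to split touching nuclei;
2. a *secondary* (cell-body) mask — each nuclear label expanded by a fixed
   radius, with overlaps partitioned by nearest nucleus so labels never
   merge;
3. spot detection for micronuclei: foreground connected components outside
   every primary region but inside a secondary region, retained only if
   (i) equivalent diameter <= min(1/3 of the owner nucleus diameter, 5 um),
   (ii) mean intensity <= 58,000 a.u. (removes apoptotic/mitotic bodies),
   and (iii) the owner nucleus itself survives the border (30 um),
   intensity and size exclusion filters.

"Diameter" throughout is the equivalent circular diameter derived from
object area; coordinates are 0-based pixel indices scaled by the pixel
size, and the border rule applies to centroids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

from .io import FieldImage

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "nucleus_id",
    "area_um2",
    "eq_diameter_um",
    "mean_intensity",
    "cx_um",
    "cy_um",
    "border_excluded",
    "intensity_excluded",
    "size_excluded",
]

MN_COLUMNS = [
    "mn_id",
    "owner_id",
    "eq_diameter_um",
    "mean_intensity",
    "cx_um",
    "cy_um",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Filter constants and segmentation knobs (lengths um, areas um^2).

    The three headline filters are the micronucleus size cap (relative 1/3
    and absolute 5 um), the 58,000 a.u. mean-intensity cap, and the 30 um
    image-periphery exclusion; the nuclear-area assay additionally requires
    at least ``min_nuclei_per_condition`` retained nuclei.
    """

    pixel_size: float = 0.323
    mn_relative_diameter_cap: float = 1.0 / 3.0
    mn_absolute_diameter_cap: float = 5.0
    mn_min_diameter: float = 1.0  # floor below which spots are noise specks
    intensity_cap: float = 58000.0
    border_margin: float = 30.0
    cell_mask_dilation: float = 10.0
    nucleus_area_band: tuple[float, float] = (40.0, 1500.0)
    min_nucleus_diameter: float = 7.0  # smaller objects are spot candidates
    watershed_min_distance: float = 6.0  # um between split markers
    min_nuclei_per_condition: int = 200

    def validate(self) -> None:
        for name in (
            "pixel_size",
            "mn_absolute_diameter_cap",
            "mn_min_diameter",
            "border_margin",
            "cell_mask_dilation",
            "min_nucleus_diameter",
            "watershed_min_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.mn_relative_diameter_cap < 1:
            raise ValueError("mn_relative_diameter_cap must lie in (0, 1)")
        if not 0 < self.intensity_cap <= 65535:
            raise ValueError("intensity_cap must lie in (0, 65535]")
        lo, hi = self.nucleus_area_band
        if not 0 < lo < hi:
            raise ValueError("nucleus_area_band must satisfy 0 < min < max")
        if self.min_nuclei_per_condition < 1:
            raise ValueError("min_nuclei_per_condition must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImagingConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "nucleus_area_band" in raw:
            raw["nucleus_area_band"] = tuple(raw["nucleus_area_band"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path


@dataclass
class QCReport:
    """Outcome of the nuclear-area minimum-count gate."""

    n_retained: int
    n_total: int
    required: int
    passed: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _foreground_mask(pixels: np.ndarray) -> np.ndarray:
    """Otsu foreground with per-object hole filling; blank images yield none."""
    if pixels.max() == pixels.min():
        return np.zeros(pixels.shape, dtype=bool)
    t = threshold_otsu(pixels)
    mask = pixels > t
    if not mask.any() or mask.all():
        return np.zeros(pixels.shape, dtype=bool)
    return ndi.binary_fill_holes(mask)


def _split_labels(mask: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Watershed split of touching objects seeded at distance-transform peaks."""
    components, n = ndi.label(mask)
    if n == 0:
        return components
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance,
        min_distance=max(1, min_distance_px),
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return components
    return watershed(-distance, markers, mask=mask)


def segment_nuclei(
    image: FieldImage, config: ImagingConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build the primary (nuclear) label mask and per-nucleus record table.

    Objects whose equivalent diameter falls below
    ``config.min_nucleus_diameter`` are left out of the primary mask (they
    are micronucleus candidates, not nuclei). Each record carries the three
    exclusion flags; exactly the rows with all flags False enter downstream
    statistics.
    """
    config.validate()
    if image.pixel_size is None or image.pixel_size <= 0:
        raise ValueError("image is uncalibrated: pixel_size must be set")
    ps = image.pixel_size
    pixels = image.pixels
    mask = _foreground_mask(pixels)
    labels_raw = _split_labels(mask, int(round(config.watershed_min_distance / ps)))

    hx, wx = image.extent_um[0], image.extent_um[1]
    nuclear_labels = np.zeros_like(labels_raw)
    rows = []
    next_id = 0
    for region in regionprops(labels_raw, intensity_image=pixels):
        area_um2 = region.area * ps * ps
        eq_d = math.sqrt(4.0 * area_um2 / math.pi)
        if eq_d < config.min_nucleus_diameter:
            continue
        next_id += 1
        nuclear_labels[labels_raw == region.label] = next_id
        cy, cx = region.centroid
        cx_um, cy_um = cx * ps, cy * ps
        edge_dist = min(cx_um, cy_um, wx - cx_um, hx - cy_um)
        lo, hi = config.nucleus_area_band
        rows.append(
            {
                "nucleus_id": next_id,
                "area_um2": area_um2,
                "eq_diameter_um": eq_d,
                "mean_intensity": float(region.intensity_mean),
                "cx_um": cx_um,
                "cy_um": cy_um,
                "border_excluded": bool(edge_dist <= config.border_margin),
                "intensity_excluded": bool(region.intensity_mean > config.intensity_cap),
                "size_excluded": bool(area_um2 < lo or area_um2 > hi),
            }
        )
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return nuclear_labels, cells


def retained(cells: pd.DataFrame) -> pd.DataFrame:
    """Rows passing all three exclusion filters."""
    if cells.empty:
        return cells
    keep = ~(
        cells["border_excluded"] | cells["intensity_excluded"] | cells["size_excluded"]
    )
    return cells[keep]


def build_cell_mask(nuclear_labels: np.ndarray, config: ImagingConfig) -> np.ndarray:
    """Secondary (cell-body) mask: nearest-nucleus partition of a fixed dilation."""
    config.validate()
    if nuclear_labels.max() == 0:
        return np.zeros_like(nuclear_labels)
    distance_px = config.cell_mask_dilation / config.pixel_size
    return expand_labels(nuclear_labels, distance=distance_px)


def detect_micronuclei(
    image: FieldImage,
    nuclear_labels: np.ndarray,
    cell_labels: np.ndarray,
    cells: pd.DataFrame,
    config: ImagingConfig,
) -> pd.DataFrame:
    """Spot detection with the three inclusion filters.

    Candidates are foreground components outside every primary region and
    inside a secondary region; a candidate overlapping two secondary regions
    is assigned to the nucleus with the nearest centroid (logged, never an
    error). Retention requires the combined size cap, the intensity cap, and
    a non-excluded owner nucleus.
    """
    config.validate()
    ps = image.pixel_size
    mask = _foreground_mask(image.pixels)
    spot_mask = mask & (nuclear_labels == 0)
    spot_labels, n_spots = ndi.label(spot_mask)
    if n_spots == 0:
        return pd.DataFrame(columns=MN_COLUMNS)

    by_id = cells.set_index("nucleus_id") if not cells.empty else None
    rows = []
    mn_id = 0
    for region in regionprops(spot_labels, intensity_image=image.pixels):
        area_um2 = region.area * ps * ps
        eq_d = math.sqrt(4.0 * area_um2 / math.pi)
        if eq_d < config.mn_min_diameter:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        under = cell_labels[rr, cc]
        owners = np.unique(under[under > 0])
        if owners.size == 0:
            continue  # outside every cell body
        cy, cx = region.centroid
        cx_um, cy_um = cx * ps, cy * ps
        if owners.size == 1:
            owner = int(owners[0])
        else:
            # spans two secondary regions: nearest nucleus centroid wins
            cands = by_id.loc[[int(o) for o in owners]]
            d2 = (cands["cx_um"] - cx_um) ** 2 + (cands["cy_um"] - cy_um) ** 2
            owner = int(d2.idxmin())
            logger.info(
                "micronucleus candidate at (%.1f, %.1f) um spans %d cell bodies; "
                "assigned to nucleus %d",
                cx_um,
                cy_um,
                owners.size,
                owner,
            )
        if by_id is None or owner not in by_id.index:
            continue
        own = by_id.loc[owner]
        if own["border_excluded"] or own["intensity_excluded"] or own["size_excluded"]:
            continue
        cap = min(
            config.mn_relative_diameter_cap * own["eq_diameter_um"],
            config.mn_absolute_diameter_cap,
        )
        if eq_d > cap:
            continue
        if region.intensity_mean > config.intensity_cap:
            continue
        mn_id += 1
        rows.append(
            {
                "mn_id": mn_id,
                "owner_id": owner,
                "eq_diameter_um": eq_d,
                "mean_intensity": float(region.intensity_mean),
                "cx_um": cx_um,
                "cy_um": cy_um,
            }
        )
    return pd.DataFrame(rows, columns=MN_COLUMNS)


def extract_nuclear_areas(
    cells: pd.DataFrame, config: ImagingConfig
) -> tuple[np.ndarray, QCReport]:
    """Areas (um^2) of non-excluded nuclei plus the minimum-count QC gate.

    A condition with fewer than ``min_nuclei_per_condition`` retained nuclei
    is flagged as a QC failure (a report, not an exception); callers decide
    whether to proceed.
    """
    config.validate()
    kept = retained(cells)
    areas = kept["area_um2"].to_numpy(dtype=float) if not kept.empty else np.array([])
    report = QCReport(
        n_retained=int(len(areas)),
        n_total=int(len(cells)),
        required=config.min_nuclei_per_condition,
        passed=len(areas) >= config.min_nuclei_per_condition,
    )
    return areas, report


def analyze_field(
    image: FieldImage, config: ImagingConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: segment, build cell mask, detect micronuclei.

    The image's own calibration wins if it differs from ``config.pixel_size``.
    """
    if abs(config.pixel_size - image.pixel_size) > 1e-12:
        config = replace(config, pixel_size=image.pixel_size)
    nuclear_labels, cells = segment_nuclei(image, config)
    cell_labels = build_cell_mask(nuclear_labels, config)
    mn = detect_micronuclei(image, nuclear_labels, cell_labels, cells, config)
    return cells, mn
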