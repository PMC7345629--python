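"""Image-quality metrics: SMR, SCR, their uncertainties, localization error.

Contrast metrics are evaluated on the squared intensity map (the display
convention for all reconstructions herein):

* SMR = 20 log10(S_max / C_mean) — peak tumor response over mean clutter.
* SCR = 20 log10(S_max / C_max) — peak tumor response over peak clutter.

``S_max`` is the maximum over the tumor region, a disc of radius
``r_t + 5 mm`` around the known tumor position (the margin absorbs tumor
placement uncertainty); the clutter region is the breast disc minus the
tumor region.  A reconstruction is "identifiable" iff SCR > 0, i.e. the
image maximum lies in the known tumor region.

Uncertainties: sigma(S_max) is the standard deviation of tumor-region pixels
at or above the region's 75th-percentile intensity; sigma(C_max) likewise at
the clutter region's 95th percentile; C_mean is taken as exact.  These are
propagated to dB to first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .geometry import Image, ScanConfig

__all__ = [
    "MetricRegions",
    "MetricReport",
    "smr",
    "scr",
    "metric_uncertainties",
    "localization_error",
    "evaluate",
    "report_table",
]

TUMOR_MARGIN_M = 0.005  # tumor-region radius = r_t + 5 mm

_DB = 20.0 / np.log(10.0)  # first-order dB propagation factor


@dataclass
class MetricRegions:
    """Pixel masks for metric evaluation on one reconstruction grid.

    ``tumor_mask``: pixels within ``tumor_radius + 5 mm`` of the known tumor
    centre (clipped to the breast disc); ``breast_mask``: pixels inside the
    assumed circular breast; ``clutter_mask``: breast minus tumor.
    """

    tumor_center: tuple
    tumor_radius: float
    tumor_mask: np.ndarray
    breast_mask: np.ndarray
    clutter_mask: np.ndarray
    pixel_coords: np.ndarray  # (n_pixels, 2), row-major
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.tumor_mask.any() or not self.clutter_mask.any():
            raise InvalidArgumentError("tumor and clutter masks must be nonempty")
        if np.any(self.tumor_mask & self.clutter_mask):
            raise InvalidArgumentError("tumor and clutter masks must be disjoint")

    @classmethod
    def from_config(
        cls,
        config: ScanConfig,
        tumor_center: tuple,
        tumor_radius: float,
        breast_radius: float | None = None,
        margin: float = TUMOR_MARGIN_M,
    ) -> "MetricRegions":
        coords = config.pixel_coords()
        rb = config.breast_radius if breast_radius is None else breast_radius
        center = np.asarray(tumor_center, dtype=float)
        d_breast = np.hypot(coords[:, 0], coords[:, 1])
        d_tumor = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
        breast = d_breast <= rb
        tumor = (d_tumor <= tumor_radius + margin) & breast
        return cls(
            tumor_center=(float(center[0]), float(center[1])),
            tumor_radius=float(tumor_radius),
            tumor_mask=tumor,
            breast_mask=breast,
            clutter_mask=breast & ~tumor,
            pixel_coords=coords,
            pixel_size=config.pixel_size,
        )


@dataclass
class MetricReport:
    """One row of a Table-style metric report for a single reconstruction."""

    smr_db: float
    scr_db: float
    smr_sigma_db: float
    scr_sigma_db: float
    localization_error_mm: float
    identifiable: bool


def _display(image: Image | np.ndarray, square: bool) -> np.ndarray:
    vals = image.values if isinstance(image, Image) else np.asarray(image, dtype=float)
    flat = vals.ravel()
    return flat**2 if square else flat


def smr(image: Image | np.ndarray, regions: MetricRegions, square: bool = True) -> float:
    """Signal-to-mean ratio in dB; +inf when the mean clutter response is zero."""
    v = _display(image, square)
    s_max = v[regions.tumor_mask].max()
    c_mean = v[regions.clutter_mask].mean()
    if c_mean == 0:
        return np.inf
    return 20.0 * np.log10(s_max / c_mean)


def scr(image: Image | np.ndarray, regions: MetricRegions, square: bool = True) -> float:
    """Signal-to-clutter ratio in dB; +inf when the peak clutter response is zero."""
    v = _display(image, square)
    s_max = v[regions.tumor_mask].max()
    c_max = v[regions.clutter_mask].max()
    if c_max == 0:
        return np.inf
    return 20.0 * np.log10(s_max / c_max)


def _upper_tail_std(values: np.ndarray, percentile: float, tail: str = "upper") -> float:
    """Std of the pixels at/above (default) or below the percentile cutoff.

    Returns NaN when fewer than 2 pixels survive the cutoff (undefined).
    ``tail="lower"`` preserves the literal "within the percentile" reading as
    an option.
    """
    cutoff = np.percentile(values, percentile)  # linear interpolation
    sel = values >= cutoff if tail == "upper" else values <= cutoff
    subset = values[sel]
    if subset.size < 2:
        return np.nan
    return float(np.std(subset))


def metric_uncertainties(
    image: Image | np.ndarray,
    regions: MetricRegions,
    square: bool = True,
    tail: str = "upper",
) -> tuple:
    """First-order dB uncertainties (sigma_SMR, sigma_SCR).

    sigma_S from the tumor region's >= 75th-percentile pixels, sigma_C from
    the clutter region's >= 95th-percentile pixels; C_mean exact.  NaN flags
    an undefined uncertainty (fewer than 2 pixels above a cutoff).
    """
    v = _display(image, square)
    tumor = v[regions.tumor_mask]
    clutter = v[regions.clutter_mask]
    s_max = tumor.max()
    c_max = clutter.max()
    sigma_s = _upper_tail_std(tumor, 75.0, tail)
    sigma_c = _upper_tail_std(clutter, 95.0, tail)
    if s_max == 0 or np.isnan(sigma_s):
        return np.nan, np.nan
    smr_sigma = _DB * sigma_s / s_max
    if c_max == 0 or np.isnan(sigma_c):
        return smr_sigma, np.nan
    scr_sigma = _DB * np.sqrt((sigma_s / s_max) ** 2 + (sigma_c / c_max) ** 2)
    return smr_sigma, scr_sigma


def localization_error(
    image: Image | np.ndarray, regions: MetricRegions, square: bool = True
) -> float:
    """Distance (mm) from the in-breast intensity maximum to the tumor centre.

    The argmax is searched over the breast mask only; exact ties are broken
    toward the smallest distance.  NaN for an all-zero image.
    """
    v = _display(image, square)
    masked = v[regions.breast_mask]
    if masked.max() == 0:
        return np.nan
    peak = masked.max()
    coords = regions.pixel_coords[regions.breast_mask]
    at_peak = coords[masked == peak]
    center = np.asarray(regions.tumor_center)
    dists = np.hypot(at_peak[:, 0] - center[0], at_peak[:, 1] - center[1])
    return float(dists.min() * 1e3)


def evaluate(
    image: Image | np.ndarray, regions: MetricRegions, square: bool = True
) -> MetricReport:
    """Full metric report for one reconstruction."""
    smr_db = smr(image, regions, square)
    scr_db = scr(image, regions, square)
    sig_smr, sig_scr = metric_uncertainties(image, regions, square)
    return MetricReport(
        smr_db=smr_db,
        scr_db=scr_db,
        smr_sigma_db=sig_smr,
        scr_sigma_db=sig_scr,
        localization_error_mm=localization_error(image, regions, square),
        identifiable=bool(scr_db > 0),
    )


def report_table(reports: dict) -> pd.DataFrame:
    """Tabulate {label: MetricReport} as one row per scan x method."""
    rows = []
    for label, rep in reports.items():
        rows.append(
            {
                "label": label,
                "smr_db": rep.smr_db,
                "smr_sigma_db": rep.smr_sigma_db,
                "scr_db": rep.scr_db,
                "scr_sigma_db": rep.scr_sigma_db,
                "loc_err_mm": rep.localization_error_mm,
                "identifiable": rep.identifiable,
            }
        )
    return pd.DataFrame(rows)
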