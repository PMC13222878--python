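"""Zymogram quantification: calibration, hotspots, compartments.

The membrane grey values are calibrated against standards of known
activity (ordinary least squares, grey = slope·activity + intercept) and
inverted to per-pixel activity in nmol cm⁻² h⁻¹. A *hotspot* is a pixel
whose grey value strictly exceeds the region-of-interest mean plus two
standard deviations (sample convention, n−1 denominator), and the hotspot
extent of a region is

    %hotspot area = 100 · N_hotspot / (N_hotspot + N_background)

i.e. the hotspot fraction of the ROI pixel count. An ``eq1_as_printed``
audit switch instead divides by (N_hotspot − N_background), reproducing a
formula that circulates in print with the denominator sign flipped; it is
off by default because that form can be negative and is read here as a
typo for the total-ROI denominator.

Compartments are derived from the root footprint: rhizoplane = the
footprint itself, rhizosphere = a band of ``band_width_px`` around it
(morphological dilation with the 8-connected / chessboard structuring
element, footprint subtracted), background = the remaining ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .datatypes import CompartmentMasks, ValidationError, Zymogram

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "HotspotResult",
    "ActivityMap",
    "fit_calibration",
    "grey_to_activity",
    "hotspot_threshold",
    "detect_hotspots",
    "segment_compartments",
    "compartment_stats",
]


@dataclass
class CalibrationCurve:
    """Linear grey-value ↔ activity calibration.

    slope has units grey per (nmol cm⁻² h⁻¹); intercept is in grey units.
    """

    slope: float
    intercept: float
    r_squared: float
    standards: list[tuple[float, float]]

    def invert(self, grey: np.ndarray) -> np.ndarray:
        if self.slope == 0:
            raise ValidationError("calibration slope is 0; curve not invertible")
        return (np.asarray(grey, dtype=float) - self.intercept) / self.slope


@dataclass
class HotspotResult:
    threshold: float
    mask: np.ndarray
    percent_area: float
    n_hotspot_px: int
    n_background_px: int


@dataclass
class ActivityMap:
    """Per-pixel enzyme activity (nmol cm⁻² h⁻¹) plus clamping bookkeeping."""

    activity: np.ndarray
    pixel_size: float
    n_clamped: int = 0


def fit_calibration(standards: list[tuple[float, float]]) -> CalibrationCurve:
    """OLS fit of grey = slope·activity + intercept over (activity, grey) pairs."""
    if len(standards) < 2:
        raise ValidationError("need at least 2 calibration standards")
    activity = np.asarray([s[0] for s in standards], dtype=float)
    grey = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(activity).size < 2:
        raise ValidationError("calibration standards have identical activities; "
                              "the fitted curve would not be invertible")
    res = stats.linregress(activity, grey)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=[(float(a), float(g)) for a, g in standards],
    )


def grey_to_activity(z: Zymogram, c: CalibrationCurve) -> ActivityMap:
    """Invert the calibration per pixel; negative activities clamp to 0.

    The number of clamped pixels is logged and kept on the result.
    """
    activity = c.invert(z.image)
    negative = activity < 0
    n_clamped = int(negative.sum())
    if n_clamped:
        log.info("clamped %d negative activity pixels to 0", n_clamped)
        activity = np.where(negative, 0.0, activity)
    return ActivityMap(activity=activity, pixel_size=z.pixel_size, n_clamped=n_clamped)


def hotspot_threshold(z: Zymogram, roi: np.ndarray) -> float:
    """Mean + 2·SD of the grey values inside the ROI (sample SD, ddof=1)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != z.image.shape:
        raise ValidationError("ROI shape does not match the image")
    values = z.image[roi].astype(float)
    if values.size == 0:
        raise ValidationError("empty ROI")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()) + 2.0 * sd


def detect_hotspots(
    z: Zymogram,
    roi: np.ndarray,
    eq1_as_printed: bool = False,
) -> HotspotResult:
    """Pixels strictly above the mean+2SD threshold, and their % area.

    ``eq1_as_printed`` switches the denominator to N_hotspot − N_background
    (audit only; can be negative or undefined).
    """
    roi = np.asarray(roi, dtype=bool)
    threshold = hotspot_threshold(z, roi)
    mask = (z.image > threshold) & roi
    n_hot = int(mask.sum())
    n_bg = int(roi.sum()) - n_hot
    if eq1_as_printed:
        denom = n_hot - n_bg
        percent = 100.0 * n_hot / denom if denom != 0 else float("nan")
    else:
        percent = 100.0 * n_hot / (n_hot + n_bg)
    return HotspotResult(
        threshold=threshold,
        mask=mask,
        percent_area=float(percent),
        n_hotspot_px=n_hot,
        n_background_px=n_bg,
    )


def segment_compartments(
    root_mask: np.ndarray,
    band_width_px: int,
    roi: np.ndarray,
) -> CompartmentMasks:
    """Partition the ROI into rhizoplane / rhizosphere band / background.

    The rhizosphere is the chessboard-dilation of the root footprint by
    ``band_width_px`` minus the footprint, clipped to the ROI.
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if band_width_px < 1:
        raise ValidationError("band_width_px must be ≥ 1")
    if not root_mask.any():
        raise ValidationError("empty root mask")
    if (root_mask & ~roi).any():
        raise ValidationError("root mask extends outside the ROI")
    # chessboard-distance dilation by b = binary dilation with a
    # (2b+1)×(2b+1) square structuring element
    size = 2 * band_width_px + 1
    dilated = ndimage.binary_dilation(root_mask, structure=np.ones((size, size), bool))
    rhizoplane = root_mask & roi
    rhizosphere = dilated & ~root_mask & roi
    background = roi & ~dilated
    masks = CompartmentMasks(rhizoplane=rhizoplane, rhizosphere=rhizosphere,
                             background=background)
    masks.check_covers(roi)
    return masks


def compartment_stats(
    a: ActivityMap,
    masks: CompartmentMasks,
    zymogram: Zymogram | None = None,
    threshold_mode: str = "local",
) -> dict[str, dict[str, float]]:
    """Mean ± SD activity and % hotspot area per compartment.

    ``threshold_mode="local"`` recomputes the mean+2SD threshold within
    each compartment; ``"global"`` applies the whole-ROI threshold
    everywhere. Hotspot percentages require the original grey image
    (``zymogram``); if omitted only activity statistics are reported.
    Empty compartments report NaN (undefined), never 0.
    """
    if threshold_mode not in ("local", "global"):
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    out: dict[str, dict[str, float]] = {}
    global_result = None
    if zymogram is not None and threshold_mode == "global":
        global_result = detect_hotspots(zymogram, masks.union())
    for name, mask in masks.items():
        n = int(mask.sum())
        entry: dict[str, float] = {"n_px": float(n)}
        if n == 0:
            entry.update(mean_activity=float("nan"), sd_activity=float("nan"),
                         percent_hotspot=float("nan"))
            out[name] = entry
            continue
        vals = a.activity[mask]
        entry["mean_activity"] = float(vals.mean())
        entry["sd_activity"] = float(vals.std(ddof=1)) if n > 1 else 0.0
        if zymogram is not None:
            if threshold_mode == "local":
                res = detect_hotspots(zymogram, mask)
                entry["percent_hotspot"] = res.percent_area
                entry["threshold"] = res.threshold
            else:
                hot = (zymogram.image > global_result.threshold) & mask
                entry["percent_hotspot"] = 100.0 * float(hot.sum()) / n
                entry["threshold"] = global_result.threshold
        out[name] = entry
    return out
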