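"""Clonogenic colony detection and survival quantification.

The detector mirrors a classic ImageJ particle-analysis macro: rolling-ball
background subtraction (radius 115 px), Gaussian blur (sigma 2 px), global
threshold, 8-connected component labeling, then a physical-unit filter
keeping objects with area >= 5000 um^2 and circularity >= 0.5. Circularity is
4*pi*area/perimeter^2 with a Crofton perimeter estimate, which stays close to
1 for digitized disks.

Survival quantities follow the standard clonogenic definitions: plating
efficiency is colonies per cell plated at 0 Gy, and the surviving fraction at
dose d is the colony yield at d normalized to plating efficiency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from scipy import ndimage
from skimage import filters, measure, restoration, transform
from sklearn.base import BaseEstimator

__all__ = [
    "ColonyDetector",
    "detect_colonies",
    "circularity",
    "surviving_fraction",
    "ClonogenicCurve",
    "subtract_background",
]


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity ``4*pi*area / perimeter**2`` (1.0 for an ideal disk)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    return 4.0 * np.pi * area / perimeter**2


def _shrink_factor(radius: float) -> int:
    # ImageJ-style: large balls roll on a shrunken image, then the
    # background is upsampled; keeps the cost independent of the radius.
    if radius > 100:
        return 8
    if radius > 30:
        return 4
    if radius > 10:
        return 2
    return 1


def subtract_background(image: np.ndarray, radius: float = 115.0) -> np.ndarray:
    """Rolling-ball background subtraction.

    A ball of the given radius rolls under the intensity surface; the highest
    surface it reaches is the background estimate, which is subtracted. For
    radii above 10 px the ball rolls on a proportionally shrunken copy of the
    image and the background is resized back, trading sub-pixel accuracy of
    the smooth background for speed.
    """
    image = np.asarray(image, dtype=float)
    shrink = _shrink_factor(radius)
    if shrink == 1:
        background = restoration.rolling_ball(image, radius=radius)
    else:
        small_shape = (
            max(1, int(np.ceil(image.shape[0] / shrink))),
            max(1, int(np.ceil(image.shape[1] / shrink))),
        )
        small = transform.resize(
            image, small_shape, order=1, anti_aliasing=True, preserve_range=True
        )
        bg_small = restoration.rolling_ball(small, radius=max(1.0, radius / shrink))
        background = transform.resize(
            bg_small, image.shape, order=1, preserve_range=True
        )
    return image - background


class ColonyDetector(BaseEstimator):
    """Colony detector over grayscale well images.

    Parameters
    ----------
    pixel_size_um:
        Physical pixel size in micrometres; required because the area filter
        is defined in um^2. May also be passed to :meth:`fit`.
    rolling_ball_radius_px, gaussian_sigma_px:
        Background-subtraction ball radius and blur sigma, in pixels.
    min_area_um2, min_circularity:
        Object filters; a detected object is ``kept`` iff it passes both.
    threshold:
        ``"otsu"`` (default) or ``"fixed"`` with ``threshold_value``. With
        Otsu a robust background floor (median + ``robust_floor_k`` scaled
        MADs of the background-subtracted image) guards against splitting a
        colony-free background into spurious foreground.

    Fitted attributes
    -----------------
    features_ : DataFrame of all detected objects with ``kept`` flags.
    count_ : number of kept colonies.
    mask_, labels_ : foreground mask and label image.
    threshold_value_ : threshold actually applied.
    """

    def __init__(
        self,
        pixel_size_um: float | None = None,
        rolling_ball_radius_px: float = 115.0,
        gaussian_sigma_px: float = 2.0,
        min_area_um2: float = 5000.0,
        min_circularity: float = 0.5,
        threshold: str = "otsu",
        threshold_value: float | None = None,
        fill_holes: bool = True,
        robust_floor_k: float = 6.0,
    ):
        self.pixel_size_um = pixel_size_um
        self.rolling_ball_radius_px = rolling_ball_radius_px
        self.gaussian_sigma_px = gaussian_sigma_px
        self.min_area_um2 = min_area_um2
        self.min_circularity = min_circularity
        self.threshold = threshold
        self.threshold_value = threshold_value
        self.fill_holes = fill_holes
        self.robust_floor_k = robust_floor_k

    # -- internal steps ----------------------------------------------------

    def _threshold(self, blurred: np.ndarray) -> float:
        if self.threshold == "fixed":
            if self.threshold_value is None:
                raise ValueError("threshold='fixed' requires threshold_value")
            return float(self.threshold_value)
        if self.threshold != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold!r}")
        finite = blurred[np.isfinite(blurred)]
        if np.ptp(finite) == 0:
            return np.inf  # constant image: no foreground
        otsu = filters.threshold_otsu(finite)
        med = np.median(finite)
        mad_sigma = 1.4826 * np.median(np.abs(finite - med))
        return float(max(otsu, med + self.robust_floor_k * mad_sigma))

    # -- estimator API -----------------------------------------------------

    def fit(self, image: np.ndarray, pixel_size_um: float | None = None):
        """Run the full pipeline on one image; returns self."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
        px = pixel_size_um if pixel_size_um is not None else self.pixel_size_um
        if px is None or px <= 0:
            raise ValueError(
                "pixel_size_um is required (area filter is in physical units)"
            )

        subtracted = subtract_background(image, self.rolling_ball_radius_px)
        blurred = ndimage.gaussian_filter(subtracted, self.gaussian_sigma_px)
        self.threshold_value_ = self._threshold(blurred)
        mask = blurred > self.threshold_value_
        if self.fill_holes:
            mask = ndimage.binary_fill_holes(mask)

        labels = measure.label(mask, connectivity=2)  # 8-connected
        px_area = px * px

        records = []
        for region in measure.regionprops(labels):
            area_um2 = region.area * px_area
            perim_um = region.perimeter_crofton * px
            circ = circularity(area_um2, perim_um) if perim_um > 0 else 0.0
            kept = area_um2 >= self.min_area_um2 and circ >= self.min_circularity
            records.append(
                {
                    "label": region.label,
                    "area_um2": area_um2,
                    "perimeter_um": perim_um,
                    "circularity": circ,
                    "centroid_row": region.centroid[0],
                    "centroid_col": region.centroid[1],
                    "kept": kept,
                }
            )

        self.features_ = pd.DataFrame(
            records,
            columns=[
                "label", "area_um2", "perimeter_um", "circularity",
                "centroid_row", "centroid_col", "kept",
            ],
        )
        self.count_ = int(self.features_["kept"].sum())
        self.mask_ = mask
        self.labels_ = labels
        return self

    def detect(self, image: np.ndarray, pixel_size_um: float | None = None) -> pd.DataFrame:
        """Fit on ``image`` and return the feature table."""
        return self.fit(image, pixel_size_um=pixel_size_um).features_


def detect_colonies(
    image: np.ndarray, pixel_size_um: float, **params
) -> tuple[pd.DataFrame, int]:
    """Functional wrapper: feature table plus kept-colony count."""
    detector = ColonyDetector(pixel_size_um=pixel_size_um, **params).fit(image)
    return detector.features_, detector.count_


# ---------------------------------------------------------------------------
# clonogenic survival
# ---------------------------------------------------------------------------


@dataclass
class ClonogenicCurve:
    """Dose -> surviving fraction series for one clonogenic assay.

    ``table`` has columns dose_Gy, cells_plated, colony_count,
    surviving_fraction. ``alpha``/``beta`` hold an optional linear-quadratic
    fit SF(D) = exp(-alpha*D - beta*D^2) obtained by least squares on log SF —
    an extension beyond the plain per-dose quantification.
    """

    table: pd.DataFrame
    plating_efficiency: float
    alpha: float | None = None
    beta: float | None = None

    def fit_linear_quadratic(self) -> "ClonogenicCurve":
        doses = self.table["dose_Gy"].to_numpy(dtype=float)
        sf = self.table["surviving_fraction"].to_numpy(dtype=float)
        ok = sf > 0
        design = np.column_stack([doses[ok], doses[ok] ** 2])
        coef, *_ = np.linalg.lstsq(design, -np.log(sf[ok]), rcond=None)
        self.alpha, self.beta = float(coef[0]), float(coef[1])
        return self

    def predict(self, dose_Gy: np.ndarray) -> np.ndarray:
        if self.alpha is None:
            raise ValueError("call fit_linear_quadratic first")
        dose = np.asarray(dose_Gy, dtype=float)
        return np.exp(-self.alpha * dose - self.beta * dose**2)


def surviving_fraction(curve_input: pd.DataFrame) -> ClonogenicCurve:
    """Compute plating efficiency and per-dose surviving fractions.

    ``curve_input`` needs columns ``dose_Gy``, ``cells_plated`` and
    ``colony_count`` including an unirradiated (0 Gy) row with a nonzero
    colony count, from which the plating efficiency is taken.
    """
    required = {"dose_Gy", "cells_plated", "colony_count"}
    missing = required - set(curve_input.columns)
    if missing:
        raise ValueError(f"curve input is missing columns: {sorted(missing)}")
    table = curve_input.copy().sort_values("dose_Gy").reset_index(drop=True)

    zero = table[table["dose_Gy"] == 0]
    if zero.empty:
        raise ValueError("a 0 Gy condition is required to define plating efficiency")
    colonies0 = float(zero["colony_count"].sum())
    plated0 = float(zero["cells_plated"].sum())
    if colonies0 <= 0:
        raise ValueError("zero colonies at 0 Gy: plating efficiency undefined")
    pe = colonies0 / plated0

    table["plating_efficiency"] = pe
    table["surviving_fraction"] = (
        table["colony_count"] / table["cells_plated"]
    ) / pe
    return ClonogenicCurve(table=table, plating_efficiency=pe)
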