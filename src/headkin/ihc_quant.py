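"""Semi-automated H-DAB immunohistochemistry quantification.

Colour deconvolution separates the hematoxylin counterstain from the DAB
chromogen in optical-density (OD) space; APP-positive axonal bulbs are then
counted per calibrated field (877 x 660 um) on the thresholded DAB channel,
and IgG extravasation is reported as the mean percent of DAB-positive pixel
area across fields.

Conventions
-----------
Pixel intensity ``I`` (8-bit, white slide I0 = 255) maps to optical density
``OD = -log10((I + 1) / 255)``; the +1 guards log(0) at fully opaque pixels.
Unmixing inverts the 3x3 stain matrix whose rows are unit OD vectors over
(R, G, B).  The DAB channel is rendered to the familiar inverted 8-bit scale
``255 * (1 - 10**-OD)`` (0 = no stain, 255 = opaque), on which thresholds —
"the intensity of the lightest accepted positive bulb" — are expressed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import InvalidSpecError, InvalidStainsError, InvalidThresholdError

log = logging.getLogger(__name__)

#: Published H-DAB stain OD vectors (hematoxylin, DAB) over (R, G, B).
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])

#: Default field extent, microns (width, height).
FIELD_SIZE_UM = (877.0, 660.0)

STAIN_NAMES = ("hematoxylin", "dab", "residual")


@dataclass
class StainMatrix:
    """Rows are unit optical-density vectors for hematoxylin, DAB, residual."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise InvalidStainsError("stain matrix must be 3x3")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.any(norms == 0):
            raise InvalidStainsError("stain vectors must be non-zero")
        self.matrix = self.matrix / norms[:, None]
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > 1e8:
            raise InvalidStainsError(f"stain matrix is singular (cond={cond:.3g})")
        log.debug("stain matrix condition number %.3g", cond)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """Ruifrok-Johnston hematoxylin + DAB with an orthogonal residual."""
        residual = np.cross(_HEMATOXYLIN, _DAB)
        return cls(np.vstack([_HEMATOXYLIN, _DAB, residual]))


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an RGB image (float or 8-bit)."""
    I = np.asarray(rgb, dtype=float)
    return -np.log10((I + 1.0) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Exact float inverse of :func:`rgb_to_od` (Beer-Lambert synthesis)."""
    return 255.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0


def mix_stains(concentrations: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Compose stain OD concentrations (..., 3) into a float RGB image."""
    od = np.asarray(concentrations, dtype=float) @ stains.matrix
    return od_to_rgb(od)


@dataclass
class DeconvolutionResult:
    od: dict  # stain name -> OD image
    rendering: dict  # stain name -> inverted 8-bit rendering (0 = unstained)
    clipped_fraction: float


def color_deconvolve(rgb: np.ndarray, stains: StainMatrix | None = None) -> DeconvolutionResult:
    """Unmix an RGB micrograph into per-stain OD channels.

    Negative unmixed concentrations (noise outside the stain simplex) are
    clipped to zero; the clipped fraction is logged and returned.
    """
    stains = stains or StainMatrix.hdab()
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.size == 0:
        raise InvalidSpecError("expected a non-empty (H, W, 3) RGB image")
    od = rgb_to_od(rgb)
    conc = od @ stains.inverse
    clipped = float(np.mean(conc < -1e-12))
    if clipped:
        log.debug("clipped %.2f%% negative unmixed OD values", 100 * clipped)
    conc = np.clip(conc, 0.0, None)
    ods = {name: conc[..., i] for i, name in enumerate(STAIN_NAMES)}
    renderings = {
        name: np.clip(np.round(255.0 * (1.0 - np.power(10.0, -ods[name]))), 0, 255).astype(np.uint8)
        for name in STAIN_NAMES
    }
    return DeconvolutionResult(ods, renderings, clipped)


@dataclass
class FieldObject:
    label: int
    area_um2: float
    equivalent_diameter_um: float
    centroid_px: tuple
    touches_border: bool


@dataclass
class CountResult:
    count: int
    objects: list = field(default_factory=list)
    n_border: int = 0
    threshold: float = 0.0


@dataclass
class IHCField:
    """One calibrated RGB micrograph plus optional synthesis ground truth."""

    rgb: np.ndarray
    microns_per_pixel: float
    field_size_um: tuple = FIELD_SIZE_UM
    truth: dict | None = None

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise InvalidSpecError("microns_per_pixel must be positive")
        h, w = self.rgb.shape[:2]
        exp_w, exp_h = self.field_size_um
        if abs(w * self.microns_per_pixel - exp_w) > 0.01 * exp_w or \
           abs(h * self.microns_per_pixel - exp_h) > 0.01 * exp_h:
            raise InvalidSpecError(
                "pixel dimensions x calibration disagree with the stated field size by >1%"
            )

    def dab_intensity(self, stains: StainMatrix | None = None) -> np.ndarray:
        """Inverted 8-bit DAB rendering (0 = unstained, 255 = opaque DAB)."""
        return color_deconvolve(self.rgb, stains).rendering["dab"]


def app_count(
    field_: IHCField,
    threshold: float,
    size_filter_um: tuple = (2.0, 50.0),
    stains: StainMatrix | None = None,
    include_border: bool = True,
) -> CountResult:
    """Count APP-positive axonal bulbs on the thresholded DAB channel.

    The DAB channel (inverted 8-bit) is binarized at ``threshold``,
    8-connected components are extracted, and objects are kept when their
    equivalent diameter falls inside ``size_filter_um`` (microns).  Objects
    touching the field border are counted once (included) by default; the
    number of such objects is logged.
    """
    dab = field_.dab_intensity(stains)
    if not 0 <= threshold <= 255:
        raise InvalidThresholdError(f"threshold {threshold} outside the 8-bit channel range")
    lo, hi = size_filter_um
    binary = dab >= threshold
    labels = measure.label(binary, connectivity=2)
    mpp = field_.microns_per_pixel
    h, w = binary.shape
    objects = []
    n_border = 0
    for region in measure.regionprops(labels):
        eq_um = region.equivalent_diameter_area * mpp
        if not (lo <= eq_um <= hi):
            continue
        minr, minc, maxr, maxc = region.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        if border:
            n_border += 1
            if not include_border:
                continue
        objects.append(
            FieldObject(region.label, region.area * mpp * mpp, eq_um,
                        tuple(region.centroid), border)
        )
    if n_border:
        log.debug("%d objects touch the field border (include_border=%s)",
                  n_border, include_border)
    return CountResult(len(objects), objects, n_border, float(threshold))


def igg_percent_area(
    fields: list[IHCField],
    threshold: float,
    stains: StainMatrix | None = None,
) -> float:
    """Mean percent of DAB-positive pixels over a fixed background threshold.

    The protocol expectation is six images per region; any other count is
    accepted with a warning.
    """
    if not fields:
        raise InvalidSpecError("need at least one field")
    if len(fields) != 6:
        log.warning("IgG protocol expects 6 images per region; got %d", len(fields))
    if not 0 <= threshold <= 255:
        raise InvalidThresholdError(f"threshold {threshold} outside the 8-bit channel range")
    percents = [
        100.0 * float(np.mean(f.dab_intensity(stains) >= threshold)) for f in fields
    ]
    return float(np.mean(percents))


def threshold_from_reference(reference_pixels, background_pixels=None) -> float:
    """Threshold = intensity of the lightest accepted positive bulb.

    ``reference_pixels`` are inverted-8-bit DAB values sampled from bulbs a
    rater accepted as positive; the minimum over the set becomes the global
    threshold.  When a background sample is supplied, the margin between the
    threshold and the background's maximum is logged as a fragility
    diagnostic.
    """
    ref = np.asarray(reference_pixels, dtype=float).ravel()
    if ref.size == 0:
        raise InvalidSpecError("reference pixel set is empty")
    thr = float(ref.min())
    if background_pixels is not None:
        bg = np.asarray(background_pixels, dtype=float).ravel()
        if bg.size:
            log.info("threshold %.1f; margin to background max %.1f", thr, thr - bg.max())
    return thr
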