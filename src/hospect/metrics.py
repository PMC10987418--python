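"""Image-quality scoring: VOIs, contrast recovery, contrast-to-noise, FWHM.

Contrast recovery for a hot sphere i is the measured-to-true concentration
ratio relative to background,

    CRC_i = (m_i / a_i) / (m_bg / a_bg),

with m the mean reconstructed value and a the true concentration in each
region.  CRC curves over x = sphere diameter / FWHM are summarized by the
sigmoid S(x) = 1 / (1 + exp(-b (x - c))) - d, whose plateau amplitude is
fixed at 1 because CRC tends to 1 for spheres much larger than the system
resolution.  Contrast-to-noise for sphere j is

    CNR_j = |mean_j - mean_bg| / sd_bg,

with the sample (n-1) standard deviation over background voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .phantom import LABEL_BACKGROUND, LABEL_WALL, VoxelPhantom, _FIRST_SPHERE_LABEL

__all__ = [
    "VoiSet",
    "CrcCurve",
    "SigmoidFit",
    "make_vois",
    "crc",
    "cnr",
    "fit_sigmoid",
    "sigmoid",
    "measure_fwhm",
]


@dataclass
class VoiSet:
    """Sphere and background volumes of interest with true concentrations."""

    sphere_masks: dict[int, np.ndarray]  # label -> boolean mask
    background_mask: np.ndarray
    true_conc: dict[int, float]  # label -> MBq/ml (includes background label)

    def __post_init__(self) -> None:
        if not self.background_mask.any():
            raise ValueError("background VOI is empty")
        occupied = self.background_mask.copy()
        for label, m in self.sphere_masks.items():
            if not m.any():
                raise ValueError(f"sphere VOI {label} is empty")
            if (m & occupied).any():
                raise ValueError(f"sphere VOI {label} overlaps another VOI")
            occupied |= m


@dataclass
class CrcCurve:
    """CRC per sphere against x = sphere diameter / system FWHM."""

    x: np.ndarray
    crc: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.crc = np.asarray(self.crc, dtype=float)
        if np.any(self.x <= 0):
            raise ValueError("x values must be positive")
        if not np.all(np.isfinite(self.crc)):
            raise ValueError("CRC values must be finite")


@dataclass
class SigmoidFit:
    b: float
    c: float
    d: float
    residual_ss: float
    a: float = 1.0  # fixed plateau

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(x, self.b, self.c, self.d)


def sigmoid(x: np.ndarray, b: float, c: float, d: float) -> np.ndarray:
    """S(x) = 1 / (1 + exp(-b (x - c))) - d, the fixed-plateau CRC model."""
    return 1.0 / (1.0 + np.exp(-b * (np.asarray(x, dtype=float) - c))) - d


def make_vois(
    phantom: VoxelPhantom,
    erosion_margin: int = 1,
    bg_radius_mm: float = 25.0,
    bg_height_mm: float = 40.0,
) -> VoiSet:
    """Sphere VOIs (labels eroded to avoid border voxels) and a background
    cylinder about the phantom axis in the sphere-center plane."""
    labels = phantom.labels
    sphere_labels = sorted(
        int(v) for v in np.unique(labels) if _FIRST_SPHERE_LABEL <= v < LABEL_WALL
    )
    if not sphere_labels:
        raise ValueError("phantom has no sphere labels")
    struct = ndimage.generate_binary_structure(3, 1)
    sphere_masks: dict[int, np.ndarray] = {}
    for lab in sphere_labels:
        mask = labels == lab
        if erosion_margin > 0:
            mask = ndimage.binary_erosion(mask, struct, iterations=erosion_margin)
        if not mask.any():
            raise ValueError(
                f"erosion margin {erosion_margin} empties the VOI of sphere label {lab}"
            )
        sphere_masks[lab] = mask

    z, y, x = phantom.grid.center_mesh()
    cylinder = (y**2 + x**2 <= bg_radius_mm**2) & (
        np.abs(z - phantom.sphere_plane_z) <= bg_height_mm / 2.0
    )
    bg_mask = cylinder & (labels == LABEL_BACKGROUND)
    if not bg_mask.any():
        raise ValueError("background VOI is empty")

    true_conc = {lab: phantom.region_conc[lab] for lab in sphere_labels}
    true_conc[LABEL_BACKGROUND] = phantom.region_conc[LABEL_BACKGROUND]
    return VoiSet(sphere_masks=sphere_masks, background_mask=bg_mask, true_conc=true_conc)


def crc(volume: np.ndarray, vois: VoiSet) -> dict[int, float]:
    """Contrast recovery coefficient per sphere label."""
    m_bg = float(volume[vois.background_mask].mean())
    a_bg = vois.true_conc[LABEL_BACKGROUND]
    if m_bg == 0:
        raise ZeroDivisionError("background measurement is zero; CRC undefined")
    out = {}
    for lab, mask in vois.sphere_masks.items():
        m_s = float(volume[mask].mean())
        out[lab] = (m_s / vois.true_conc[lab]) / (m_bg / a_bg)
    return out


def cnr(volume: np.ndarray, vois: VoiSet) -> dict[int, float]:
    """Contrast-to-noise ratio per sphere label."""
    bg = volume[vois.background_mask]
    if bg.size < 2:
        raise ValueError("background VOI must contain at least 2 voxels")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ZeroDivisionError("background standard deviation is zero; CNR undefined")
    m_bg = float(bg.mean())
    return {
        lab: abs(float(volume[mask].mean()) - m_bg) / sd
        for lab, mask in vois.sphere_masks.items()
    }


def fit_sigmoid(
    curve: CrcCurve,
    init: tuple[float, float, float] = (1.0, 2.0, 0.0),
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1e-8, 1e-8, 0.0),
        (np.inf, np.inf, 1.0),
    ),
) -> SigmoidFit:
    """Least-squares fit of the fixed-plateau sigmoid to a CRC curve."""
    if curve.x.size < 3:
        raise ValueError("need at least 3 points to fit the sigmoid")

    def residuals(p: np.ndarray) -> np.ndarray:
        return sigmoid(curve.x, *p) - curve.crc

    res = optimize.least_squares(residuals, x0=np.asarray(init, float), bounds=bounds)
    if not res.success:
        raise RuntimeError(f"sigmoid fit did not converge: {res.message}; best {res.x}")
    b, c, d = (float(v) for v in res.x)
    return SigmoidFit(b=b, c=c, d=d, residual_ss=float(np.sum(res.fun**2)))


def measure_fwhm(profile: np.ndarray, pixel_size_mm: float = 1.0) -> float:
    """FWHM of a single-peaked profile by linear interpolation of the
    half-maximum crossings, after baseline (minimum) subtraction."""
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be a 1D array with at least 3 samples")
    p = p - p.min()
    peak = int(np.argmax(p))
    half = p[peak] / 2.0
    if half <= 0:
        raise ValueError("profile has no peak above baseline")

    # walk down from the peak to the first crossing on each side
    left = None
    for i in range(peak, 0, -1):
        if p[i - 1] < half <= p[i]:
            t = (half - p[i - 1]) / (p[i] - p[i - 1])
            left = (i - 1) + t
            break
    right = None
    for i in range(peak, p.size - 1):
        if p[i + 1] < half <= p[i]:
            t = (p[i] - half) / (p[i] - p[i + 1])
            right = i + t
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossing found on one side of the peak")
    return (right - left) * pixel_size_mm
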