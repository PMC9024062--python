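"""SD-OCT reconstruction with numerical dispersion compensation.

The processing chain is the standard one: background subtraction, analytic
signal construction (the fringes are already sampled on a uniform k grid),
multiplication by the phase-correction term

    phi_bar(k) = -a2 (k - k0)^2 - a3 (k - k0)^3,

FFT to depth, magnitude, positive-depth half.  Reconstructing the same raw
frame with a ladder of second-order coefficients produces the co-registered
"compensation stack" that feeds both the ground-truth stitcher and the
restoration network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import hilbert

from .sim import KGrid, RawFrame, dispersion_phase

__all__ = [
    "BScan",
    "CompensationStack",
    "subtract_background",
    "linearize_k",
    "analytic_spectrum",
    "apply_phase_correction",
    "reconstruct_ascan",
    "reconstruct_bscan",
    "build_compensation_stack",
    "log_display",
]

SUPPORTED_CHANNELS = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class BScan:
    """Reconstructed cross-sectional image, Z = P/2 rows, depth downward."""

    image: np.ndarray
    scale: str = "linear"  # "linear" | "log"
    depth_pitch_um: float = float("nan")
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("image must be 2-D (depth x A-lines)")
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise ValueError("image values must be finite and non-negative")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        object.__setattr__(self, "image", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class CompensationStack:
    """N co-registered B-scans of one frame, one per correction coefficient."""

    coefficients: tuple[float, ...]
    bscans: tuple[BScan, ...]

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        bscans = tuple(self.bscans)
        if len(coeffs) != len(bscans) or not coeffs:
            raise ValueError("need one B-scan per coefficient (N >= 1)")
        if len(coeffs) > 1 and np.any(np.diff(coeffs) <= 0):
            raise ValueError("coefficients must be strictly increasing")
        shapes = {b.shape for b in bscans}
        scales = {b.scale for b in bscans}
        if len(shapes) != 1 or len(scales) != 1:
            raise ValueError("all B-scans must share shape and scale")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "bscans", bscans)

    def __len__(self) -> int:
        return len(self.bscans)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bscans[0].shape

    def images(self) -> np.ndarray:
        """(N, Z, A) array view of the stack."""
        return np.stack([b.image for b in self.bscans])

    def mid_channel(self) -> BScan:
        return self.bscans[len(self.bscans) // 2]


def subtract_background(frame: RawFrame) -> RawFrame:
    """Remove the per-detector-pixel mean across A-lines (DC background)."""
    if frame.n_alines < 2:
        raise ValueError("background subtraction needs at least 2 A-lines")
    bg = frame.fringes.mean(axis=1, keepdims=True)
    return replace(frame, fringes=frame.fringes - bg)


def linearize_k(
    fringes_lambda: np.ndarray,
    wavelengths_nm: np.ndarray,
    grid: KGrid,
    kind: str = "cubic",
) -> np.ndarray:
    """Resample wavelength-uniform fringes onto the uniform k grid.

    ``kind='cubic'`` uses a cubic spline per A-line; ``'linear'`` is the
    cheaper fallback.  Detector data come sorted by ascending wavelength,
    i.e. descending k, so the columns are flipped for interpolation.
    """
    k_of_lambda = 2.0 * np.pi * 1e3 / np.asarray(wavelengths_nm, dtype=float)
    order = np.argsort(k_of_lambda)
    k_src = k_of_lambda[order]
    f = np.atleast_2d(np.asarray(fringes_lambda, dtype=float).T).T[order, :]
    if kind == "cubic":
        out = CubicSpline(k_src, f, axis=0)(grid.k_values)
    elif kind == "linear":
        out = interp1d(k_src, f, axis=0, fill_value="extrapolate")(grid.k_values)
    else:
        raise ValueError("kind must be 'cubic' or 'linear'")
    return out if fringes_lambda.ndim == 2 else out[:, 0]


def analytic_spectrum(fringes: np.ndarray) -> np.ndarray:
    """Complex analytic signal along the detector axis (negative z suppressed)."""
    return hilbert(fringes, axis=0)


def apply_phase_correction(
    complex_spectrum: np.ndarray,
    grid: KGrid,
    a2: float,
    a3: float = 0.0,
    mode: str = "pixel-index",
) -> np.ndarray:
    """Multiply by exp(i*phi_bar(k)) with phi_bar = -a2 u^2 - a3 u^3.

    A layer whose fringe carries +a2 u^2 in its phase is exactly compensated
    by correcting with the *same* coefficient a2.  Pure phase: the magnitude
    spectrum is untouched.
    """
    if complex_spectrum.shape[0] != grid.n_pixels:
        raise ValueError("spectrum length does not match grid")
    phase = -dispersion_phase(grid, a2, a3, mode)
    factor = np.exp(1j * phase)
    if complex_spectrum.ndim == 2:
        factor = factor[:, None]
    return complex_spectrum * factor


def _depth_transform(corrected: np.ndarray, n_pixels: int, pad_factor: int) -> np.ndarray:
    n_fft = n_pixels * pad_factor
    depth = np.abs(np.fft.fft(corrected, n=n_fft, axis=0))
    return depth[: n_fft // 2]


def reconstruct_ascan(
    fringe: np.ndarray,
    grid: KGrid,
    a2: float = 0.0,
    a3: float = 0.0,
    mode: str = "pixel-index",
    pad_factor: int = 1,
) -> np.ndarray:
    """Depth intensity profile (length P/2 * pad_factor) of one fringe.

    Expects a background-subtracted, k-linear fringe.  ``pad_factor`` > 1
    zero-pads the FFT for sub-pixel peak/FWHM analysis.
    """
    fringe = np.asarray(fringe, dtype=float)
    if not np.all(np.isfinite(fringe)):
        raise ValueError("fringe contains non-finite values")
    spec = analytic_spectrum(fringe[:, None] if fringe.ndim == 1 else fringe)
    spec = apply_phase_correction(spec, grid, a2, a3, mode)
    depth = _depth_transform(spec, grid.n_pixels, pad_factor)
    return depth[:, 0] if fringe.ndim == 1 else depth


def reconstruct_bscan(
    frame: RawFrame,
    a2: float = 0.0,
    a3: float = 0.0,
    mode: str = "pixel-index",
    subtract_bg: bool = True,
) -> BScan:
    """Column-wise reconstruction of a raw frame at one correction coefficient."""
    if subtract_bg:
        frame = subtract_background(frame)
    img = reconstruct_ascan(frame.fringes, frame.grid, a2, a3, mode)
    return BScan(
        img,
        scale="linear",
        depth_pitch_um=frame.grid.depth_pitch_um,
        provenance={
            "a2": float(a2),
            "a3": float(a3),
            "mode": mode,
            "volume_index": frame.volume_index,
            "frame_index": frame.frame_index,
            "bscan_index": frame.bscan_index,
            "repeat_index": frame.repeat_index,
        },
    )


def coefficient_ladder(c_min: float, c_max: float, n_channels: int) -> np.ndarray:
    """Equally spaced correction coefficients; n=1 collapses to the midpoint."""
    if n_channels not in SUPPORTED_CHANNELS:
        raise ValueError(f"n_channels must be one of {SUPPORTED_CHANNELS}, got {n_channels}")
    if n_channels == 1:
        return np.array([0.5 * (c_min + c_max)])
    if not c_min < c_max:
        raise ValueError("need c_min < c_max for more than one channel")
    return np.linspace(c_min, c_max, n_channels)


def build_compensation_stack(
    frame: RawFrame,
    c_min: float,
    c_max: float,
    n_channels: int,
    mode: str = "pixel-index",
) -> CompensationStack:
    """Reconstruct one frame at n equally spaced coefficients in [c_min, c_max]."""
    coeffs = coefficient_ladder(c_min, c_max, n_channels)
    clean = subtract_background(frame)
    spec = analytic_spectrum(clean.fringes)
    bscans = []
    for c in coeffs:
        corrected = apply_phase_correction(spec, frame.grid, c, 0.0, mode)
        img = _depth_transform(corrected, frame.grid.n_pixels, 1)
        bscans.append(
            BScan(
                img,
                scale="linear",
                depth_pitch_um=frame.grid.depth_pitch_um,
                provenance={
                    "a2": float(c),
                    "a3": 0.0,
                    "mode": mode,
                    "volume_index": frame.volume_index,
                    "frame_index": frame.frame_index,
                    "bscan_index": frame.bscan_index,
                    "repeat_index": frame.repeat_index,
                },
            )
        )
    return CompensationStack(tuple(coeffs), tuple(bscans))


def log_display(bscan: BScan, floor_db: float = -60.0) -> BScan:
    """20*log10(I/max I) clipped at ``floor_db`` then rescaled to [0, 1]."""
    if bscan.scale != "linear":
        raise ValueError("log_display expects a linear-scale B-scan")
    peak = bscan.image.max()
    if peak <= 0:
        raise ValueError("cannot log-compress an all-zero image")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(bscan.image / peak)
    db = np.clip(db, floor_db, 0.0)
    img = (db - floor_db) / (-floor_db)
    prov = dict(bscan.provenance)
    prov["floor_db"] = float(floor_db)
    return BScan(img, scale="log", depth_pitch_um=bscan.depth_pitch_um, provenance=prov)
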