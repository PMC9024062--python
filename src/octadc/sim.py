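"""Physics-based synthetic SD-OCT interferogram generator.

Simulates the spectral fringes recorded by a spectrometer-based OCT system:
a broadband (Gaussian) source interferes with light back-reflected from a
layered sample, and each sample layer imprints its own optical pathlength
delay and chromatic dispersion onto the fringe phase.  The core feature is
*depth-varying* second/third-order dispersion — every layer carries its own
coefficients — which is what makes single-coefficient numerical compensation
insufficient and motivates per-depth correction.

Conventions
-----------
* Wavelengths in nm at the interface, wavenumbers in rad/um internally
  (k = 2*pi/lambda).
* ``delta_z_um`` is the *total* optical pathlength difference between the
  sample layer and the reference mirror (round trip already included).
* Pixel-index dispersion phase: ``phi(j) = a2*((j - j0)/(P/2))**2``, i.e.
  ``a2`` is the quadratic phase in radians accumulated at the edge of the
  detector grid.  This makes coefficient sweep ranges instrument-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SourceSpectrum",
    "KGrid",
    "DispersionSpec",
    "Layer",
    "LayeredSample",
    "NoiseModel",
    "RawFrame",
    "make_source_spectrum",
    "resample_to_k",
    "source_intensity_on_k",
    "dispersion_phase",
    "simulate_ascan_spectrum",
    "simulate_bscan_fringes",
    "simulate_volume",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi
# nm -> um conversion for wavenumber: k[rad/um] = 2*pi * 1e3 / lambda[nm]
_NM_PER_UM = 1e3


@dataclass(frozen=True)
class SourceSpectrum:
    """Broadband source envelope sampled on the detector's wavelength grid."""

    wavelengths_nm: np.ndarray
    intensity_au: np.ndarray
    center_wavelength_nm: float

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensity_au, dtype=float)
        if lam.ndim != 1 or lam.size != inten.size:
            raise ValueError("wavelength and intensity arrays must be 1-D and equal length")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        ic = np.interp(self.center_wavelength_nm, lam, inten)
        if ic <= 0:
            raise ValueError("intensity must be positive at the center wavelength")
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "intensity_au", inten)

    @property
    def n_pixels(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class KGrid:
    """Uniform wavenumber grid (rad/um) with its intensity-weighted center k0."""

    k_values: np.ndarray
    k0: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=float)
        dk = np.diff(k)
        if k.size < 2 or np.any(dk <= 0):
            raise ValueError("k_values must be strictly increasing")
        if np.ptp(dk) > 1e-9 * abs(dk[0]):
            raise ValueError("k grid must be uniform to 1e-9 relative")
        if not (k[0] <= self.k0 <= k[-1]):
            raise ValueError("k0 must lie inside the grid")
        object.__setattr__(self, "k_values", k)

    @property
    def n_pixels(self) -> int:
        return self.k_values.size

    @property
    def dk(self) -> float:
        return float(self.k_values[1] - self.k_values[0])

    @property
    def depth_pitch_um(self) -> float:
        """Depth sampling pitch of the FFT reconstruction, 2*pi/(P*dk)."""
        return TWO_PI / (self.n_pixels * self.dk)

    @property
    def max_depth_um(self) -> float:
        """Unambiguous single-sided depth range pi/dk."""
        return np.pi / self.dk

    def center_index(self) -> float:
        """Fractional detector-pixel index of k0."""
        return (self.k0 - self.k_values[0]) / self.dk


@dataclass(frozen=True)
class DispersionSpec:
    """Second/third-order spectral-phase coefficients of one layer.

    ``mode='pixel-index'`` (default): a2 (a3) is the quadratic (cubic) phase in
    radians at the detector grid edge.  ``mode='physical-k'``: coefficients
    multiply (k-k0)^2 and (k-k0)^3 with k in rad/um.  a2 = a3 = 0 means
    transform-limited propagation.
    """

    a2: float = 0.0
    a3: float = 0.0
    mode: str = "pixel-index"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a2) and np.isfinite(self.a3)):
            raise ValueError("dispersion coefficients must be finite")
        if self.mode not in ("pixel-index", "physical-k"):
            raise ValueError(f"unknown dispersion mode {self.mode!r}")


@dataclass(frozen=True)
class Layer:
    delta_z_um: float
    reflectivity: float
    dispersion: DispersionSpec = field(default_factory=DispersionSpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflectivity <= 1.0:
            raise ValueError("reflectivity must lie in [0, 1]")


@dataclass(frozen=True)
class LayeredSample:
    """Ordered stack of reflective layers plus lateral geometry and speckle.

    ``lateral_profile`` gives a per-A-line depth offset (um) added to every
    layer, modelling sample curvature/tilt; ``speckle_density`` is the number
    of sub-resolution random scatterers realized around each layer per A-line.
    """

    layers: tuple[Layer, ...]
    lateral_profile: np.ndarray | None = None
    speckle_density: int = 0
    speckle_spread_um: float = 8.0
    speckle_reflectivity: float = 0.05

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("sample must contain at least one layer")
        dz = [ly.delta_z_um for ly in layers]
        if np.any(np.diff(dz) <= 0):
            raise ValueError("layer delta_z must be strictly increasing")
        object.__setattr__(self, "layers", layers)
        if self.lateral_profile is not None:
            object.__setattr__(
                self, "lateral_profile", np.asarray(self.lateral_profile, dtype=float)
            )

    def offset_at(self, a_line_index: int) -> float:
        if self.lateral_profile is None:
            return 0.0
        return float(self.lateral_profile[a_line_index % self.lateral_profile.size])


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise plus optional shot noise.

    ``additive_sigma`` is the AWGN standard deviation in units of the (peak
    normalized) source intensity; ``shot_factor`` scales a signal-dependent
    Gaussian term with variance proportional to the local fringe intensity.
    """

    additive_sigma: float = 0.0
    shot_factor: float = 0.0

    @property
    def silent(self) -> bool:
        return self.additive_sigma == 0.0 and self.shot_factor == 0.0

    def apply(self, fringe: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.silent:
            return fringe
        out = fringe
        if self.additive_sigma > 0:
            out = out + rng.normal(0.0, self.additive_sigma, size=fringe.shape)
        if self.shot_factor > 0:
            sigma = np.sqrt(self.shot_factor * np.clip(fringe, 0.0, None))
            out = out + sigma * rng.standard_normal(fringe.shape)
        return out


@dataclass(frozen=True)
class RawFrame:
    """One recorded spectrogram frame: P detector pixels x A a-lines."""

    fringes: np.ndarray
    source: SourceSpectrum
    grid: KGrid
    repeats: int = 1
    frame_index: int = 0
    volume_index: int = 0
    bscan_index: int = 0
    repeat_index: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fringes, dtype=float)
        if f.ndim != 2:
            raise ValueError("fringes must be a 2-D (P x A) matrix")
        if not np.all(np.isfinite(f)):
            raise ValueError("fringes must be finite")
        if f.shape[1] < 1:
            raise ValueError("at least one A-line required")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        object.__setattr__(self, "fringes", f)

    @property
    def n_pixels(self) -> int:
        return self.fringes.shape[0]

    @property
    def n_alines(self) -> int:
        return self.fringes.shape[1]


def make_source_spectrum(
    center_wavelength_nm: float = 840.0,
    fwhm_bandwidth_nm: float = 50.0,
    n_pixels: int = 2048,
) -> SourceSpectrum:
    """Gaussian source envelope sampled linearly in wavelength.

    The grid spans center +/- 2*FWHM and the peak is normalized to 1.
    """
    if fwhm_bandwidth_nm <= 0:
        raise ValueError("bandwidth must be positive")
    if n_pixels < 16:
        raise ValueError("need at least 16 detector pixels")
    lam = np.linspace(
        center_wavelength_nm - 2.0 * fwhm_bandwidth_nm,
        center_wavelength_nm + 2.0 * fwhm_bandwidth_nm,
        int(n_pixels),
    )
    sigma2 = fwhm_bandwidth_nm**2 / (8.0 * np.log(2.0))
    inten = np.exp(-((lam - center_wavelength_nm) ** 2) / (2.0 * sigma2))
    inten /= inten.max()  # peak exactly 1 on the sampled grid
    return SourceSpectrum(lam, inten, float(center_wavelength_nm))


def resample_to_k(spectrum: SourceSpectrum) -> KGrid:
    """Uniform wavenumber grid spanning [2*pi/lambda_max, 2*pi/lambda_min].

    k0 is the intensity-weighted centroid of k (intensity interpolated onto
    the k grid), i.e. the spectral center the phase expansion is taken about.
    """
    lam = spectrum.wavelengths_nm
    k_lo = TWO_PI * _NM_PER_UM / lam[-1]
    k_hi = TWO_PI * _NM_PER_UM / lam[0]
    k = np.linspace(k_lo, k_hi, spectrum.n_pixels)
    inten_k = source_intensity_on_k_values(spectrum, k)
    total = inten_k.sum()
    k0 = float((k * inten_k).sum() / total) if total > 0 else float(0.5 * (k_lo + k_hi))
    return KGrid(k, k0)


def source_intensity_on_k_values(spectrum: SourceSpectrum, k: np.ndarray) -> np.ndarray:
    """Interpolate the source envelope onto arbitrary wavenumbers (cubic spline)."""
    lam_of_k = TWO_PI * _NM_PER_UM / k
    # spline over ascending wavelength, evaluated at lambda(k)
    spl = CubicSpline(spectrum.wavelengths_nm, spectrum.intensity_au)
    out = spl(lam_of_k)
    return np.clip(out, 0.0, None)


def source_intensity_on_k(spectrum: SourceSpectrum, grid: KGrid) -> np.ndarray:
    """Reference-arm intensity I_r(k) on the uniform k grid."""
    return source_intensity_on_k_values(spectrum, grid.k_values)


def dispersion_phase(grid: KGrid, a2: float, a3: float, mode: str = "pixel-index") -> np.ndarray:
    """Spectral phase a2*u^2 + a3*u^3 on the grid.

    In pixel-index mode u = (j - j0)/(P/2) so a2/a3 are radians at the grid
    edge; in physical-k mode u = k - k0 in rad/um.
    """
    if mode == "pixel-index":
        j = np.arange(grid.n_pixels, dtype=float)
        u = (j - grid.center_index()) / (grid.n_pixels / 2.0)
    elif mode == "physical-k":
        u = grid.k_values - grid.k0
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")
    return a2 * u**2 + a3 * u**3


def _layer_terms(
    grid: KGrid,
    ir: np.ndarray,
    layers: Sequence[Layer],
    depth_offset_um: float,
) -> np.ndarray:
    """Sum of interference terms 2*sqrt(I_n I_r) cos(k dz + phi_n(k))."""
    k = grid.k_values
    out = np.zeros_like(ir)
    for ly in layers:
        if ly.reflectivity == 0.0:
            continue
        dz = ly.delta_z_um + depth_offset_um
        if dz > grid.max_depth_um:
            log.warning(
                "layer at delta_z=%.1f um exceeds unambiguous depth range %.1f um; "
                "signal will alias",
                dz,
                grid.max_depth_um,
            )
        phase = k * dz + dispersion_phase(grid, ly.dispersion.a2, ly.dispersion.a3, ly.dispersion.mode)
        # I_n(k) = reflectivity * I_r(k)  =>  2*sqrt(I_n I_r) = 2*sqrt(r)*I_r
        out += 2.0 * np.sqrt(ly.reflectivity) * ir * np.cos(phase)
    return out


def _speckle_layers(sample: LayeredSample, rng: np.random.Generator) -> list[Layer]:
    """Sub-resolution scatterers jittered around each layer (one A-line's worth)."""
    extra: list[Layer] = []
    for ly in sample.layers:
        if sample.speckle_density <= 0:
            continue
        dz = ly.delta_z_um + rng.uniform(
            -sample.speckle_spread_um, sample.speckle_spread_um, size=sample.speckle_density
        )
        r = rng.uniform(0.0, sample.speckle_reflectivity * ly.reflectivity, size=sample.speckle_density)
        for d, rr in zip(dz, r):
            extra.append(Layer(float(d), float(rr), ly.dispersion))
    # Layer ordering is irrelevant for the sum; skip the sorted-dz invariant.
    return extra


def simulate_ascan_spectrum(
    source: SourceSpectrum,
    grid: KGrid,
    sample: LayeredSample,
    a_line_index: int = 0,
    noise_model: NoiseModel | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one spectral interferogram (length P) on the uniform k grid.

    fringe(k) = I_r(k)                          (DC background)
              + sum_n 2 sqrt(I_n I_r) cos(k dz_n + a2_n u^2 + a3_n u^3)
              + noise

    Deterministic given the same seed/generator.  Speckle scatterers are part
    of the sample geometry and are drawn from the same generator *before* the
    noise, so callers wanting shared geometry across repeats should realize
    speckle themselves (see :func:`simulate_bscan_fringes`).
    """
    if grid.n_pixels != source.n_pixels:
        raise ValueError("source and grid lengths differ")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    ir = source_intensity_on_k(source, grid)
    offset = sample.offset_at(a_line_index)
    layers = list(sample.layers)
    if sample.speckle_density > 0:
        layers += _speckle_layers(sample, rng)
    fringe = ir + _layer_terms(grid, ir, layers, offset)
    noise = noise_model or NoiseModel()
    return noise.apply(fringe, rng)


def simulate_bscan_fringes(
    source: SourceSpectrum,
    grid: KGrid,
    sample: LayeredSample,
    n_alines: int,
    noise_model: NoiseModel | None = None,
    geometry_rng: np.random.Generator | None = None,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """P x A fringe matrix with speckle geometry and noise drawn separately.

    Speckle scatterers come from ``geometry_rng`` (so repeated frames at the
    same location can share them) and detector noise from ``noise_rng``.
    """
    geometry_rng = geometry_rng or np.random.default_rng()
    noise_rng = noise_rng or np.random.default_rng()
    ir = source_intensity_on_k(source, grid)
    noise = noise_model or NoiseModel()
    cols = np.empty((grid.n_pixels, n_alines))
    for a in range(n_alines):
        layers = list(sample.layers)
        if sample.speckle_density > 0:
            layers += _speckle_layers(sample, geometry_rng)
        fringe = ir + _layer_terms(grid, ir, layers, sample.offset_at(a))
        cols[:, a] = noise.apply(fringe, noise_rng)
    return cols


def simulate_volume(
    sample_sequence: LayeredSample | Sequence[LayeredSample],
    n_bscans: int,
    a_lines_per_bscan: int,
    repeats: int = 1,
    noise_model: NoiseModel | None = None,
    rng_seed: int = 0,
    source: SourceSpectrum | None = None,
    grid: KGrid | None = None,
    volume_index: int = 0,
) -> list[RawFrame]:
    """Simulate a volume of ``n_bscans`` locations x ``repeats`` frames each.

    Repeated frames at one location share the speckle geometry and differ only
    in the detector-noise realization.  Bitwise deterministic for a given seed.
    """
    if n_bscans < 1 or repeats < 1:
        raise ValueError("n_bscans and repeats must be >= 1")
    if isinstance(sample_sequence, LayeredSample):
        samples = [sample_sequence] * n_bscans
    else:
        samples = list(sample_sequence)
        if len(samples) != n_bscans:
            raise ValueError("sample_sequence length must equal n_bscans")
    source = source or make_source_spectrum()
    grid = grid or resample_to_k(source)

    frames: list[RawFrame] = []
    idx = 0
    for b, sample in enumerate(samples):
        for rep in range(repeats):
            # speckle geometry seeded per location only -> shared across repeats
            geo = np.random.default_rng([rng_seed, volume_index, b, 0xA11])
            noi = np.random.default_rng([rng_seed, volume_index, b, rep, 0x0E])
            fr = simulate_bscan_fringes(
                source, grid, sample, a_lines_per_bscan, noise_model, geo, noi
            )
            frames.append(
                RawFrame(
                    fr,
                    source,
                    grid,
                    repeats=repeats,
                    frame_index=idx,
                    volume_index=volume_index,
                    bscan_index=b,
                    repeat_index=rep,
                )
            )
            idx += 1
    return frames
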