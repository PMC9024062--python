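"""Per-depth optimal coefficient discovery and ground-truth stitching.

Because dispersion in layered tissue varies with depth, no single correction
coefficient sharpens the whole B-scan.  The all-depth "ground truth" is
manufactured by reconstructing the same raw frame with a ladder of
coefficients, then copying from each reconstruction the depth band it
renders sharpest and stitching the bands together.  The sharpest coefficient
per band is found automatically by maximizing an intensity-concentration
sharpness score over a coefficient sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .recon import (
    BScan,
    CompensationStack,
    analytic_spectrum,
    apply_phase_correction,
    build_compensation_stack,
    coefficient_ladder,
    log_display,
    subtract_background,
    _depth_transform,
)
from .sim import RawFrame

__all__ = [
    "DepthBands",
    "TrainingPair",
    "sharpness_score",
    "estimate_optimal_coeff",
    "partition_depth_bands",
    "stitch_ground_truth",
    "build_dataset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DepthBands:
    """Contiguous, exhaustive partition of the depth axis into row intervals."""

    bands: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        bands = tuple((int(a), int(b)) for a, b in self.bands)
        if not bands:
            raise ValueError("at least one band required")
        for lo, hi in bands:
            if hi <= lo:
                raise ValueError(f"empty band [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 != hi:
                raise ValueError("bands must be contiguous with no gaps or overlaps")
        object.__setattr__(self, "bands", bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def z_rows(self) -> int:
        return self.bands[-1][1]


@dataclass(frozen=True)
class TrainingPair:
    """One network training example: multichannel input stack + stitched target."""

    inputs: np.ndarray  # (C, Z, A), log-scale, [0, 1]
    target: np.ndarray  # (Z, A), log-scale, [0, 1]
    split: str  # "train" | "test"
    coefficients: tuple[float, ...]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.inputs, dtype=np.float32)
        y = np.asarray(self.target, dtype=np.float32)
        if x.ndim != 3 or y.ndim != 2 or x.shape[1:] != y.shape:
            raise ValueError("input stack and target shapes disagree")
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")
        object.__setattr__(self, "inputs", x)
        object.__setattr__(self, "target", y)


def sharpness_score(bscan: BScan | np.ndarray, band: tuple[int, int] | None = None) -> float:
    """Normalized intensity concentration sum(I^4)/sum(I^2)^2 over a depth band.

    A single-pixel impulse scores 1; a uniform band of M pixels scores 1/M.
    Invariant to global intensity scaling.  Higher = sharper.
    """
    img = bscan.image if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    if band is not None:
        lo, hi = band
        if lo < 0 or hi > img.shape[0] or hi <= lo:
            raise ValueError(f"band [{lo}, {hi}) outside image with {img.shape[0]} rows")
        img = img[lo:hi]
    e2 = float(np.sum(img**2))
    if e2 == 0.0:
        return 0.0
    return float(np.sum(img**4)) / e2**2


def estimate_optimal_coeff(
    frame: RawFrame,
    band: tuple[int, int],
    sweep: tuple[float, float, float],
    mode: str = "pixel-index",
) -> float:
    """Correction coefficient maximizing band sharpness over a sweep.

    Brute-force sweep of ``arange(c_min, c_max, step)`` (endpoint included)
    followed by parabolic interpolation through the top score and its
    neighbours.  A flat score landscape (max/min < 1 + 1e-6) triggers a
    degenerate-landscape warning and returns the sweep midpoint.
    """
    c_min, c_max, step = sweep
    if step <= 0:
        raise ValueError("sweep step must be positive")
    coeffs = np.arange(c_min, c_max + 0.5 * step, step)
    if coeffs.size == 0:
        raise ValueError("empty coefficient sweep")
    if coeffs.size == 1:
        return float(coeffs[0])

    clean = subtract_background(frame)
    spec = analytic_spectrum(clean.fringes)
    scores = np.empty(coeffs.size)
    for i, c in enumerate(coeffs):
        corrected = apply_phase_correction(spec, frame.grid, c, 0.0, mode)
        img = _depth_transform(corrected, frame.grid.n_pixels, 1)
        scores[i] = sharpness_score(img, band)

    smin, smax = scores.min(), scores.max()
    if smin <= 0 or smax / smin < 1.0 + 1e-6:
        log.warning("degenerate sharpness landscape in band %s; returning sweep midpoint", band)
        return float(0.5 * (c_min + c_max))

    i = int(np.argmax(scores))
    if 0 < i < coeffs.size - 1:
        # parabola through the top three points
        y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            return float(coeffs[i] + np.clip(shift, -1.0, 1.0) * step)
    return float(coeffs[i])


def partition_depth_bands(
    n_bands: int,
    z_rows: int,
    boundaries: str | Sequence[int] = "auto",
) -> DepthBands:
    """Split [0, z_rows) into n contiguous bands.

    ``auto``: equal heights, remainder rows assigned to the last band.
    Explicit boundaries are the n-1 interior row indices, validated for
    contiguity.
    """
    if n_bands < 1 or n_bands > z_rows:
        raise ValueError("need 1 <= n_bands <= z_rows")
    if isinstance(boundaries, str):
        if boundaries != "auto":
            raise ValueError("boundaries must be 'auto' or an explicit sequence")
        h = z_rows // n_bands
        edges = [i * h for i in range(n_bands)] + [z_rows]
    else:
        interior = [int(b) for b in boundaries]
        if len(interior) != n_bands - 1:
            raise ValueError(f"expected {n_bands - 1} interior boundaries, got {len(interior)}")
        edges = [0] + interior + [z_rows]
        if np.any(np.diff(edges) <= 0):
            raise ValueError("explicit boundaries must be strictly increasing within (0, z_rows)")
    return DepthBands(tuple((edges[i], edges[i + 1]) for i in range(n_bands)))


def layer_aware_bands(bscan: BScan, n_bands: int) -> DepthBands:
    """Band boundaries at midpoints between the n strongest depth peaks.

    Alternative to the equal-height default when the layer positions are
    visible in a reconstruction: the mean A-scan is scanned for its n_bands
    strongest local maxima and boundaries are placed halfway between them.
    """
    from scipy.signal import find_peaks

    profile = bscan.image.mean(axis=1)
    peaks, props = find_peaks(profile, prominence=0.01 * profile.max())
    if peaks.size < n_bands:
        return partition_depth_bands(n_bands, bscan.shape[0])
    top = np.sort(peaks[np.argsort(props["prominences"])[-n_bands:]])
    interior = [(int(top[i]) + int(top[i + 1])) // 2 for i in range(n_bands - 1)]
    return partition_depth_bands(n_bands, bscan.shape[0], interior)


def stitch_ground_truth(
    stack: CompensationStack,
    bands: DepthBands,
    feather: int = 0,
) -> BScan:
    """Assemble the all-depth-compensated image from a compensation stack.

    Band i is copied from B-scan i (ascending coefficient <-> increasing
    depth).  ``feather`` > 0 blends linearly across each seam over that many
    rows; the default is a hard stitch.
    """
    if len(stack) != len(bands):
        raise ValueError(f"stack size {len(stack)} != number of bands {len(bands)}")
    z, a = stack.shape
    if bands.z_rows != z:
        raise ValueError(f"bands cover {bands.z_rows} rows but image has {z}")
    imgs = stack.images()
    out = np.empty((z, a))
    for i, (lo, hi) in enumerate(bands):
        out[lo:hi] = imgs[i, lo:hi]
    if feather > 0:
        for i, (lo, _) in enumerate(bands):
            if i == 0:
                continue
            half = feather // 2
            top = max(lo - half, 0)
            bot = min(lo + feather - half, z)
            w = np.linspace(0.0, 1.0, bot - top)[:, None]
            out[top:bot] = (1.0 - w) * imgs[i - 1, top:bot] + w * imgs[i, top:bot]
    prov = dict(stack.bscans[0].provenance)
    prov.update(
        stitched_from=list(stack.coefficients),
        bands=[list(b) for b in bands],
        feather=int(feather),
    )
    prov.pop("a2", None)
    return BScan(
        out,
        scale=stack.bscans[0].scale,
        depth_pitch_um=stack.bscans[0].depth_pitch_um,
        provenance=prov,
    )


def build_dataset(
    volumes: Sequence[Sequence[RawFrame]],
    n_channels: int,
    c_range: tuple[float, float],
    bands: DepthBands,
    n_train_volumes: int,
    gt_channels: int | None = None,
    floor_db: float = -60.0,
    feather: int = 0,
    single_channel_coeff: float | None = None,
) -> list[TrainingPair]:
    """Assemble normalized training pairs from raw volumes.

    The stitched target is always built from the ``gt_channels``-coefficient
    stack (default: one channel per depth band) regardless of the input
    channel count — the ground truth is made once; only the network input
    varies.  Splits are assigned volume-wise: a volume never contributes
    frames to both splits.  Both input and target are log-compressed and
    min-max normalized to [0, 1].
    """
    if gt_channels is None:
        gt_channels = len(bands)
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes for a train/test split")
    if not 1 <= n_train_volumes < len(volumes):
        raise ValueError("n_train_volumes must leave at least one test volume")
    c_min, c_max = c_range
    pairs: list[TrainingPair] = []
    for v, frames in enumerate(volumes):
        split = "train" if v < n_train_volumes else "test"
        for frame in frames:
            gt_stack = build_compensation_stack(frame, c_min, c_max, gt_channels)
            gt = stitch_ground_truth(gt_stack, bands, feather)
            if n_channels == gt_channels:
                in_stack = gt_stack
            elif n_channels == 1 and single_channel_coeff is not None:
                # a single-coefficient input pinned away from the midpoint
                # (e.g. at C_1, optimizing the shallowest band only)
                c = single_channel_coeff
                in_stack = build_compensation_stack(frame, c, c, 1)
            else:
                in_stack = build_compensation_stack(frame, c_min, c_max, n_channels)
            x = np.stack([log_display(b, floor_db).image for b in in_stack.bscans])
            y = log_display(gt, floor_db).image
            pairs.append(
                TrainingPair(
                    x.astype(np.float32),
                    y.astype(np.float32),
                    split,
                    in_stack.coefficients,
                    meta={
                        "volume_index": frame.volume_index,
                        "bscan_index": frame.bscan_index,
                        "repeat_index": frame.repeat_index,
                        "repeats": frame.repeats,
                        "floor_db": floor_db,
                        "normalization": "per-image log min-max [0,1]",
                    },
                )
            )
    return pairs
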