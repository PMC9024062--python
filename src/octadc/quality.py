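"""Image-quality evaluation battery: PSNR, SSIM, MS-SSIM, differential
intensity images, axial intensity-profile/PSF analysis, and the
channel-count comparison experiment.

PSNR is 10*log10(s^2 / MSE) with, by default, s taken literally as the
maximum pixel intensity of the *reconstructed* (second) image — which makes
it asymmetric in its arguments; a fixed-dynamic-range mode is provided for
conventional comparisons.  SSIM uses the standard local-statistics form with
C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2/2 and an 11x11 Gaussian window
(sigma 1.5).  MS-SSIM evaluates contrast and structure on a dyadic pyramid,
luminance at the coarsest scale only, combined with the canonical 5-scale
exponents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, find_peaks, peak_widths

__all__ = [
    "SSIMParams",
    "AxialProfile",
    "QualityReport",
    "mse",
    "psnr",
    "ssim",
    "ms_ssim",
    "average_repeats",
    "difference_image",
    "axial_profile",
    "run_channel_experiment",
]

# canonical 5-scale MS-SSIM exponents (sum to 1)
_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    n_scales: int = 5
    weights: tuple[float, ...] = _MSSSIM_WEIGHTS
    window_size: int = 11
    window_sigma: float = 1.5

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass(frozen=True)
class AxialProfile:
    """Averaged linear-scale depth profile with detected reflective peaks."""

    depth_rows: np.ndarray
    intensity: np.ndarray
    peak_rows: np.ndarray
    peak_heights: np.ndarray
    peak_fwhm_rows: np.ndarray
    n_bscans_avg: int
    n_alines_avg: int


@dataclass
class QualityReport:
    """Per-variant PSNR / MS-SSIM table (mean +/- sd) plus per-image rows."""

    rows: pd.DataFrame  # columns: variant, seed, group, psnr_db, ms_ssim
    protocol: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        agg = self.rows.groupby("variant").agg(
            psnr_mean=("psnr_db", "mean"),
            psnr_sd=("psnr_db", "std"),
            ms_ssim_mean=("ms_ssim", "mean"),
            ms_ssim_sd=("ms_ssim", "std"),
            n=("ms_ssim", "size"),
        )
        return agg.fillna(0.0)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _check_pair(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {g.shape}")
    return f, g


def mse(f: np.ndarray, g: np.ndarray) -> float:
    """Mean squared pixel-wise difference."""
    f, g = _check_pair(f, g)
    return float(np.mean((f - g) ** 2))


def psnr(f: np.ndarray, g: np.ndarray, s: float | str = "auto") -> float:
    """Peak signal-to-noise ratio 10*log10(s^2/MSE) in dB.

    ``s='auto'`` uses the maximum pixel of ``g`` (the reconstructed image);
    pass a number for fixed-dynamic-range PSNR.  Identical images return
    +inf with a warning (the formula is singular there).
    """
    f, g = _check_pair(f, g)
    err = mse(f, g)
    peak = float(np.max(g)) if isinstance(s, str) else float(s)
    if err == 0.0:
        warnings.warn("PSNR of identical images is infinite", RuntimeWarning, stacklevel=2)
        return math.inf
    return float(10.0 * np.log10(peak**2 / err))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _local_stats(x, y, params: SSIMParams):
    w = _gaussian_window(params.window_size, params.window_sigma)
    mu_x = fftconvolve(x, w, mode="valid")
    mu_y = fftconvolve(y, w, mode="valid")
    sxx = fftconvolve(x * x, w, mode="valid") - mu_x**2
    syy = fftconvolve(y * y, w, mode="valid") - mu_y**2
    sxy = fftconvolve(x * y, w, mode="valid") - mu_x * mu_y
    return mu_x, mu_y, sxx, syy, sxy


def _ssim_maps(x, y, params: SSIMParams):
    """Luminance map and combined contrast*structure map over valid windows."""
    mu_x, mu_y, sxx, syy, sxy = _local_stats(x, y, params)
    lum = (2.0 * mu_x * mu_y + params.c1) / (mu_x**2 + mu_y**2 + params.c1)
    cs = (2.0 * sxy + params.c2) / (sxx + syy + params.c2)
    return lum, cs


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean structural similarity with unit exponents (alpha = beta = gamma = 1)."""
    x, y = _check_pair(x, y)
    params = params or SSIMParams()
    if min(x.shape) < params.window_size:
        raise ValueError("image smaller than the SSIM window")
    lum, cs = _ssim_maps(x, y, params)
    return float(np.mean(lum * cs))


def _downsample2(x: np.ndarray) -> np.ndarray:
    """Low-pass by 2x2 mean then decimate by 2 (odd edges cropped)."""
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Multi-scale SSIM: contrast/structure at every scale of a dyadic
    pyramid, luminance only at the coarsest, exponent-weighted product.

    The requested number of scales is reduced (with a warning) when the
    image is too small for the window at the coarsest scale; an image too
    small for even one scale raises.
    """
    x, y = _check_pair(x, y)
    params = params or SSIMParams()
    m = params.n_scales
    min_dim = min(x.shape)
    if min_dim < params.window_size:
        raise ValueError("image smaller than the SSIM window at scale 1")
    while m > 1 and (min_dim // 2 ** (m - 1)) < params.window_size:
        m -= 1
    if m < params.n_scales:
        warnings.warn(
            f"image too small for {params.n_scales} scales; using {m}",
            RuntimeWarning,
            stacklevel=2,
        )
    weights = np.asarray(params.weights[:m], dtype=float)
    weights = weights / weights.sum()

    def _weighted(mean: float, w: float) -> float:
        # a fractional power of a negative mean is undefined; clamp to zero
        # there, but keep unit exponents exact (plain SSIM may be negative)
        if mean < 0.0 and w != 1.0:
            mean = 0.0
        return mean**w

    value = 1.0
    for j in range(m):
        lum, cs = _ssim_maps(x, y, params)
        if j == m - 1:
            # luminance enters only at the coarsest scale, via the full
            # similarity map — so one scale reduces exactly to plain SSIM
            value *= _weighted(float(np.mean(lum * cs)), weights[j])
        else:
            value *= _weighted(float(np.mean(cs)), weights[j])
            x, y = _downsample2(x), _downsample2(y)
    return float(value)


def average_repeats(images: Sequence[np.ndarray], group_size: int) -> list[np.ndarray]:
    """Group-wise pixel mean of consecutive images (repeat averaging)."""
    images = list(images)
    if group_size < 1 or len(images) % group_size != 0:
        raise ValueError(f"{len(images)} images not divisible into groups of {group_size}")
    out = []
    for i in range(0, len(images), group_size):
        out.append(np.mean(np.stack(images[i : i + group_size]), axis=0))
    return out


def difference_image(ground_truth: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Absolute pixel-wise intensity difference |GT - candidate|."""
    f, g = _check_pair(ground_truth, candidate)
    return np.abs(f - g)


def render_difference(diff: np.ndarray, cmap: str = "jet") -> np.ndarray:
    """RGBA rendering of a difference map, normalized to its own maximum."""
    import matplotlib

    peak = diff.max()
    norm = diff / peak if peak > 0 else diff
    return matplotlib.colormaps[cmap](norm)


def axial_profile(
    volume: Sequence[np.ndarray] | np.ndarray,
    column: int,
    n_bscans_avg: int = 6,
    n_alines_avg: int = 5,
    prominence_frac: float = 0.05,
) -> AxialProfile:
    """Averaged linear-scale depth profile through a volume.

    The first ``n_bscans_avg`` B-scans are pixel-averaged, then
    ``n_alines_avg`` adjacent A-lines centred on ``column`` are averaged.
    Peaks are local maxima above ``prominence_frac * max``; FWHM is measured
    by linear interpolation at half prominence-corrected height.
    """
    vol = np.stack([np.asarray(b, dtype=float) for b in volume])
    n, z, a = vol.shape
    if n_bscans_avg < 1 or n_bscans_avg > n:
        raise ValueError(f"cannot average {n_bscans_avg} B-scans from a volume of {n}")
    lo = column - n_alines_avg // 2
    hi = lo + n_alines_avg
    if lo < 0 or hi > a:
        raise ValueError(f"A-line window [{lo}, {hi}) outside image width {a}")
    mean_b = vol[:n_bscans_avg].mean(axis=0)
    profile = mean_b[:, lo:hi].mean(axis=1)
    peaks, _ = find_peaks(profile, prominence=prominence_frac * profile.max())
    if peaks.size:
        widths, _, _, _ = peak_widths(profile, peaks, rel_height=0.5)
    else:
        widths = np.array([])
    return AxialProfile(
        depth_rows=np.arange(z),
        intensity=profile,
        peak_rows=peaks.astype(float),
        peak_heights=profile[peaks] if peaks.size else np.array([]),
        peak_fwhm_rows=widths,
        n_bscans_avg=n_bscans_avg,
        n_alines_avg=n_alines_avg,
    )


def evaluate_pairs(
    predictions: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    params: SSIMParams | None = None,
) -> pd.DataFrame:
    """Per-image PSNR/MS-SSIM rows for co-indexed prediction/target lists."""
    params = params or SSIMParams()
    rows = []
    for i, (p, t) in enumerate(zip(predictions, targets)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(
                {"group": i, "psnr_db": psnr(t, p), "ms_ssim": ms_ssim(t, p, params)}
            )
    return pd.DataFrame(rows)


def run_channel_experiment(
    datasets: Mapping[int, Sequence],
    seeds: Sequence[int],
    model_config=None,
    params: SSIMParams | None = None,
    repeat_group: int = 1,
    plot_path=None,
) -> QualityReport:
    """Train one model per channel count per seed and tabulate test metrics.

    ``datasets`` maps channel count -> list of TrainingPair built from the
    *same* volumes (so targets agree across counts).  The uncompensated (UC)
    baseline is the mid-coefficient input channel, which is model- and
    seed-independent.  Repeat frames are averaged (``repeat_group``) before
    metrics, and metrics compare against the stitched ground truth.
    """
    from .adcnet import ModelConfig, build_model, predict_pairs, train

    params = params or SSIMParams()
    all_rows = []
    counts = sorted(datasets)
    # UC baseline: the zero-coefficient reconstruction, i.e. the middle
    # channel of the widest (symmetric) ladder — model- and seed-independent
    base = datasets[counts[-1]]
    test_pairs0 = [p for p in base if p.split == "test"]
    gts = average_repeats([p.target for p in test_pairs0], repeat_group)
    uc = average_repeats(
        [p.inputs[p.inputs.shape[0] // 2] for p in test_pairs0], repeat_group
    )
    uc_rows = evaluate_pairs(uc, gts, params)
    uc_rows["variant"] = "UC"
    uc_rows["seed"] = -1
    all_rows.append(uc_rows)

    for n in counts:
        pairs = datasets[n]
        train_pairs = [p for p in pairs if p.split == "train"]
        test_pairs = [p for p in pairs if p.split == "test"]
        targets = average_repeats([p.target for p in test_pairs], repeat_group)
        for seed in seeds:
            cfg = (model_config or ModelConfig()).with_updates(n_channels=n, rng_seed=int(seed))
            model = build_model(cfg)
            # validate on a small fixed subset; full-test metrics follow below
            model, _ = train(model, train_pairs, cfg, val_pairs=test_pairs[:6])
            preds = average_repeats(predict_pairs(model, test_pairs), repeat_group)
            rows = evaluate_pairs(preds, targets, params)
            rows["variant"] = f"M{n}"
            rows["seed"] = int(seed)
            all_rows.append(rows)

    report = QualityReport(
        rows=pd.concat(all_rows, ignore_index=True),
        protocol={
            "channel_counts": counts,
            "seeds": [int(s) for s in seeds],
            "repeat_group": repeat_group,
            "metric_scale": "log-compressed [0,1] images, L=1",
        },
    )
    if plot_path is not None:
        plot_channel_report(report, plot_path)
    return report


def plot_channel_report(report: QualityReport, path) -> None:
    """Bar chart of mean +/- sd MS-SSIM and PSNR per variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = report.summary()
    order = ["UC"] + sorted(
        (v for v in s.index if v != "UC"), key=lambda v: int(v[1:])
    )
    s = s.loc[[v for v in order if v in s.index]]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    finite_psnr = s["psnr_mean"].replace([np.inf, -np.inf], np.nan)
    axes[0].bar(s.index, s["ms_ssim_mean"], yerr=s["ms_ssim_sd"], color="steelblue")
    axes[0].set_ylabel("MS-SSIM")
    axes[1].bar(s.index, finite_psnr, yerr=s["psnr_sd"], color="indianred")
    axes[1].set_ylabel("PSNR (dB)")
    for ax in axes:
        ax.set_xlabel("model variant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
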