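"""Pixel-level image-quality metrics, whole-image and foreground-restricted.

Foreground-aware training deliberately changes what the model does in the
background, so whole-image scores and foreground-restricted scores must be
read together: the evaluation here computes PSNR and 3D structural
similarity both ways, plus a Fourier shell correlation (FSC) resolution
estimate.  The structural-similarity metric is standard 3D SSIM (optionally
averaged over the foreground mask); it is a stand-in for microscopy-specific
structural-similarity variants, not a reproduction of any of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .errors import EmptyForegroundError, ValidationError
from .losses import ForegroundMask

__all__ = [
    "MetricsReport",
    "psnr",
    "ssim3d",
    "frc_curve",
    "frc_resolution",
    "background_mean_abs",
    "compute_metrics",
    "NYQUIST_FLOOR",
]

NYQUIST_FLOOR = 2.0  # voxels: the finest resolvable period


def _as_volumes(target, prediction) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(target, dtype=np.float64)
    p = np.asarray(prediction, dtype=np.float64)
    if t.shape != p.shape:
        raise ValidationError(f"shape mismatch: target {t.shape}, prediction {p.shape}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValidationError("volumes must be finite")
    return t, p


def _mask_bool(mask) -> np.ndarray:
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask)
    return m.astype(bool)


def psnr(
    target,
    prediction,
    mask=None,
    cap_db: float = 100.0,
    return_flag: bool = False,
):
    """Peak signal-to-noise ratio in dB: ``10 log10(R^2 / MSE)``.

    The dynamic range R is the *target's* max - min (prediction-independent).
    With a mask, the MSE runs over masked voxels only.  A zero-MSE pair
    (identical volumes) reports the capped sentinel ``cap_db`` with
    ``capped=True`` when ``return_flag`` is set.
    """
    t, p = _as_volumes(target, prediction)
    r = float(t.max() - t.min())
    if r <= 0:
        raise ValidationError("target has zero dynamic range; PSNR undefined")
    if mask is not None:
        m = _mask_bool(mask)
        if m.shape != t.shape:
            raise ValidationError("mask shape mismatch")
        if not m.any():
            raise EmptyForegroundError("mask has no foreground voxels")
        mse = float(np.mean((t[m] - p[m]) ** 2))
    else:
        mse = float(np.mean((t - p) ** 2))
    if mse == 0.0:
        return (cap_db, True) if return_flag else cap_db
    value = min(10.0 * np.log10(r**2 / mse), cap_db)
    capped = value >= cap_db
    return (value, capped) if return_flag else value


def ssim3d(target, prediction, window: int = 7, mask=None, data_range: float | None = None):
    """Mean local 3D structural similarity, optionally over a mask.

    Local SSIM maps are computed with cubic windows (odd ``window`` >= 3,
    stabilization constants K1=0.01, K2=0.03 over the target's dynamic
    range) and averaged over all voxels or over the mask.
    """
    t, p = _as_volumes(target, prediction)
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 3, got {window}")
    if min(t.shape) < window:
        raise ValidationError(f"volume {t.shape} smaller than window {window}")
    if data_range is None:
        data_range = float(t.max() - t.min())
        if data_range <= 0:
            raise ValidationError(
                "target has zero dynamic range; pass data_range explicitly"
            )
    _, smap = structural_similarity(
        t, p, win_size=window, data_range=data_range, full=True
    )
    if mask is None:
        return float(smap.mean())
    m = _mask_bool(mask)
    if m.shape != t.shape:
        raise ValidationError("mask shape mismatch")
    if not m.any():
        raise EmptyForegroundError("mask has no foreground voxels")
    return float(smap[m].mean())


def _shell_index(shape: tuple[int, ...], n_shells: int, mode: str):
    """Frequency-magnitude bin index per FFT voxel; bin 0 is DC."""
    freqs = [np.fft.fftfreq(s) for s in shape]
    if mode == "shell":
        grids = np.meshgrid(*freqs, indexing="ij")
        r = np.sqrt(sum(g**2 for g in grids))
    elif mode == "ring":
        grids = np.meshgrid(*freqs[1:], indexing="ij")
        r = np.sqrt(sum(g**2 for g in grids))
    else:
        raise ValidationError(f"unknown FRC mode {mode!r}")
    edges = np.linspace(0.0, 0.5, n_shells + 1)
    idx = np.clip(np.digitize(r, edges[1:], right=True), 0, n_shells - 1)
    idx[r == 0] = -1  # DC excluded
    idx[r > 0.5] = -1  # corner frequencies beyond Nyquist excluded
    centers = 0.5 * (edges[:-1] + edges[1:])
    return idx, centers


def frc_curve(target, prediction, n_shells: int = 16, mode: str = "shell"):
    """Fourier shell (3D) or ring (2D, slice-averaged) correlation curve.

    Returns ``(spatial_frequencies, correlations)`` where correlations are
    the normalized cross-correlations of the two volumes' Fourier
    coefficients accumulated over concentric frequency shells.  Frequencies
    are in cycles/voxel, excluding DC.
    """
    t, p = _as_volumes(target, prediction)
    if n_shells < 4:
        raise ValidationError(f"n_shells must be >= 4, got {n_shells}")
    if mode == "shell":
        ft, fp = np.fft.fftn(t), np.fft.fftn(p)
        idx, centers = _shell_index(t.shape, n_shells, "shell")
        flat_idx = idx.ravel()
        valid = flat_idx >= 0
        num = np.bincount(
            flat_idx[valid], weights=(ft.conj() * fp).real.ravel()[valid], minlength=n_shells
        )
        d1 = np.bincount(flat_idx[valid], weights=(np.abs(ft) ** 2).ravel()[valid], minlength=n_shells)
        d2 = np.bincount(flat_idx[valid], weights=(np.abs(fp) ** 2).ravel()[valid], minlength=n_shells)
    elif mode == "ring":
        idx, centers = _shell_index(t.shape, n_shells, "ring")
        flat_idx = idx.ravel()
        valid = flat_idx >= 0
        num = np.zeros(n_shells)
        d1 = np.zeros(n_shells)
        d2 = np.zeros(n_shells)
        for z in range(t.shape[0]):
            ft, fp = np.fft.fftn(t[z]), np.fft.fftn(p[z])
            num += np.bincount(
                flat_idx[valid], weights=(ft.conj() * fp).real.ravel()[valid], minlength=n_shells
            )
            d1 += np.bincount(flat_idx[valid], weights=(np.abs(ft) ** 2).ravel()[valid], minlength=n_shells)
            d2 += np.bincount(flat_idx[valid], weights=(np.abs(fp) ** 2).ravel()[valid], minlength=n_shells)
    else:
        raise ValidationError(f"unknown FRC mode {mode!r}")

    denom = np.sqrt(d1 * d2)
    corr = np.zeros(n_shells)
    np.divide(num, denom, out=corr, where=denom > 0)
    populated = np.bincount(flat_idx[valid], minlength=n_shells) > 0
    return centers[populated], corr[populated]


def frc_resolution(
    target,
    prediction,
    n_shells: int = 16,
    criterion: float = 1.0 / 7.0,
    mode: str = "shell",
    return_flag: bool = False,
):
    """Resolution estimate (voxels) from the shell-correlation criterion crossing.

    The correlation curve is scanned from low to high frequency for the
    first drop below ``criterion`` (default 1/7); the crossing frequency is
    linearly interpolated between shells and reported as a real-space period
    ``1 / f`` in voxels.  If the curve never drops below the criterion the
    Nyquist floor (2 voxels) is returned with ``at_floor=True``.
    """
    freqs, corr = frc_curve(target, prediction, n_shells=n_shells, mode=mode)
    below = np.flatnonzero(corr < criterion)
    if len(below) == 0:
        return (NYQUIST_FLOOR, True) if return_flag else NYQUIST_FLOOR
    i = int(below[0])
    if i == 0:
        f_cross = freqs[0]
    else:
        f0, f1 = freqs[i - 1], freqs[i]
        c0, c1 = corr[i - 1], corr[i]
        f_cross = f0 + (c0 - criterion) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
    resolution = max(1.0 / max(f_cross, 1e-12), NYQUIST_FLOOR)
    return (float(resolution), False) if return_flag else float(resolution)


def background_mean_abs(prediction, mask) -> float:
    """Mean absolute intensity over background (mask == 0) voxels."""
    p = np.asarray(prediction, dtype=np.float64)
    m = _mask_bool(mask)
    if m.shape != p.shape:
        raise ValidationError("mask shape mismatch")
    bg = ~m
    if not bg.any():
        raise EmptyForegroundError("mask covers the whole volume; no background voxels")
    return float(np.abs(p[bg]).mean())


@dataclass
class MetricsReport:
    """Named scalar metrics for one prediction/target pair."""

    psnr_whole: float
    psnr_fg: float | None
    ssim3d_whole: float
    ssim3d_fg: float | None
    frc_resolution: float
    mask_fraction: float
    psnr_capped: bool = False
    frc_at_floor: bool = False

    def to_row(self) -> dict:
        return {
            "psnr_whole_db": self.psnr_whole,
            "psnr_fg_db": self.psnr_fg,
            "ssim3d_whole": self.ssim3d_whole,
            "ssim3d_fg": self.ssim3d_fg,
            "frc_resolution_voxels": self.frc_resolution,
            "mask_fraction": self.mask_fraction,
            "psnr_capped": self.psnr_capped,
            "frc_at_floor": self.frc_at_floor,
        }


def compute_metrics(
    target,
    prediction,
    mask=None,
    window: int = 7,
    n_shells: int = 16,
) -> MetricsReport:
    """Full metric panel for one prediction/target pair.

    If no mask is given it is derived from the target by Otsu thresholding.
    Foreground-restricted entries are None when the mask is empty.
    """
    from .losses import foreground_mask, otsu_threshold

    t, p = _as_volumes(target, prediction)
    if mask is None:
        mask = foreground_mask(t, otsu_threshold(t))
    m = _mask_bool(mask)

    psnr_whole, capped = psnr(t, p, return_flag=True)
    frc, at_floor = frc_resolution(t, p, n_shells=n_shells, return_flag=True)
    psnr_fg = ssim_fg = None
    if m.any():
        psnr_fg = psnr(t, p, mask=m)
        ssim_fg = ssim3d(t, p, window=window, mask=m)
    return MetricsReport(
        psnr_whole=psnr_whole,
        psnr_fg=psnr_fg,
        ssim3d_whole=ssim3d(t, p, window=window),
        ssim3d_fg=ssim_fg,
        frc_resolution=frc,
        mask_fraction=float(m.mean()),
        psnr_capped=capped,
        frc_at_floor=at_floor,
    )
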