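"""Foreground estimation and the Spotlight training objective.

Virtual-staining models regress a fluorescence volume from a transmitted-light
volume.  Trained with a plain pixel-wise loss they spend most of their
capacity reproducing background noise, because background dominates the voxel
count in 3D stacks.  The Spotlight objective instead

1. estimates the foreground of the *target* fluorescence volume by Otsu
   thresholding (:func:`otsu_threshold`, :func:`foreground_mask`),
2. restricts the pixel-wise loss to that mask (:func:`masked_mse`),
3. soft-thresholds the *prediction* with a normalized tunable sigmoid
   (:func:`tunable_sigmoid`, :func:`soft_foreground`) and scores its shape
   against the binary mask with a smoothed Dice loss (:func:`dice_loss`),

and combines the two terms as ``lambda * L_mmse + (1 - lambda) * L_dice``
(:func:`spotlight_loss`).

All loss terms are differentiable in the prediction: pass a
:class:`~spotlight3d._autodiff.Tensor` to get a tensor back (with the graph
attached); pass a plain numpy array to get a float.  Volumes are expected to
be min--max normalized to [0, 1] before loss computation
(:func:`normalize_volume`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .errors import (
    DegenerateHistogramError,
    EmptyForegroundError,
    InvalidParameterError,
    ValidationError,
)

__all__ = [
    "ForegroundMask",
    "SpotlightLossConfig",
    "LossValue",
    "normalize_volume",
    "otsu_threshold",
    "foreground_mask",
    "masked_mse",
    "tunable_sigmoid",
    "soft_foreground",
    "dice_loss",
    "spotlight_loss",
]


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite values")


def validate_volume(volume, name: str = "volume") -> np.ndarray:
    """Validate a 3D intensity stack (Z, Y, X) and return it as float64."""
    a = np.asarray(volume, dtype=np.float64)
    if a.ndim != 3:
        raise ValidationError(f"{name} must be 3D (Z, Y, X), got ndim={a.ndim}")
    if min(a.shape) < 1:
        raise ValidationError(f"{name} has an empty dimension: {a.shape}")
    _check_finite(a, name)
    return a


def normalize_volume(volume) -> tuple[np.ndarray, tuple[float, float]]:
    """Min--max normalize a volume to [0, 1].

    Returns the normalized volume and the ``(min, max)`` pair needed to invert
    the normalization at prediction time.  A constant volume maps to zeros.
    """
    a = np.asarray(volume, dtype=np.float64)
    _check_finite(a, "volume")
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        return (a - lo) / (hi - lo), (lo, hi)
    return np.zeros_like(a), (lo, hi)


@dataclass(frozen=True)
class ForegroundMask:
    """Binary foreground mask M derived from a target volume at threshold T.

    ``mask[z, y, x] == 1`` iff the source voxel intensity is >= ``threshold``.
    """

    mask: np.ndarray
    threshold: float

    def __post_init__(self):
        m = np.asarray(self.mask)
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be in {0, 1}")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SpotlightLossConfig:
    """Tunable parameters of the Spotlight objective.

    Parameters
    ----------
    lambda_weight:
        Convex weight on the masked-MSE term; ``1 - lambda_weight`` goes to
        the Dice term.  In [0, 1].
    sigmoid_k:
        Sharpness of the normalized tunable sigmoid used to soft-threshold
        the prediction.  Admissible range (-1, 1); negative values sharpen
        toward a step, 0 is the identity.  Practical default range (-1, 0].
    dice_eps:
        Smoothing constant in the Dice denominator; > 0.
    center_policy:
        How the prediction enters the sigmoid's domain when
        soft-thresholding.  ``"otsu_center"`` (default) recentres the
        prediction so the transition sits at the target's Otsu threshold —
        matching the mask the Dice loss compares against.  ``"fixed_half"``
        puts the transition at 0.5.  ``"direct"`` applies sigma_k to the
        [0, 1] prediction as-is, leaving the transition just above zero for
        negative k.
    """

    lambda_weight: float = 0.5
    sigmoid_k: float = -0.9
    dice_eps: float = 1e-6
    center_policy: str = "otsu_center"

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise InvalidParameterError(f"lambda_weight must be in [0, 1], got {self.lambda_weight}")
        if not -1.0 < self.sigmoid_k < 1.0:
            raise InvalidParameterError(f"sigmoid_k must be in (-1, 1), got {self.sigmoid_k}")
        if not self.dice_eps > 0:
            raise InvalidParameterError(f"dice_eps must be > 0, got {self.dice_eps}")
        if self.center_policy not in ("direct", "otsu_center", "fixed_half"):
            raise InvalidParameterError(f"unknown center_policy {self.center_policy!r}")


@dataclass
class LossValue:
    """A scalar loss with its named components.

    ``value == lambda * components['mmse'] + (1 - lambda) * components['dice']``
    within floating tolerance.  When the prediction was a Tensor, ``tensor``
    holds the differentiable total for ``backward()``.
    """

    value: float
    components: dict = field(default_factory=dict)
    tensor: Tensor | None = None


# -- foreground estimation -------------------------------------------------


def otsu_threshold(volume, n_bins: int = 256) -> float:
    """Otsu's threshold: the cut maximizing inter-class variance.

    The histogram has ``n_bins`` equal-width bins over [min, max] of the
    volume.  Every cut position between adjacent bins is evaluated; ties are
    broken toward the lowest threshold.  The returned T is the lower edge of
    the first foreground bin, so ``volume >= T`` reproduces the histogram
    split exactly.

    Raises
    ------
    DegenerateHistogramError
        If the volume is constant (no cut separates two classes).
    """
    a = np.asarray(volume, dtype=np.float64)
    _check_finite(a, "volume")
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise DegenerateHistogramError(
            f"constant volume (all values {lo}): Otsu threshold undefined"
        )
    counts, edges = np.histogram(a.ravel(), bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()

    w0 = np.cumsum(counts)[:-1]  # class-0 weight for cut after bin c
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] + counts[-1] * centers[-1] - csum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=-np.inf)
    # ties (e.g. cuts separated only by empty bins) resolve to the lowest
    # threshold; the tolerance absorbs floating-point noise in the cumsums
    best = between.max()
    c = int(np.flatnonzero(between >= best - 1e-9 * abs(best))[0])
    return float(edges[c + 1])


def foreground_mask(volume, threshold: float) -> ForegroundMask:
    """Binary mask ``M = (volume >= threshold)``; the comparison is inclusive."""
    a = validate_volume(volume)
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    return ForegroundMask(mask=(a >= threshold).astype(np.uint8), threshold=float(threshold))


# -- loss terms ------------------------------------------------------------


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, ForegroundMask):
        return mask.mask.astype(np.float64)
    return np.asarray(mask, dtype=np.float64)


def _loss_output(result: Tensor, differentiable: bool):
    return result if differentiable else float(result.data)


def masked_mse(target, prediction, mask):
    """Foreground-masked mean squared error.

    ``L = sum(M * (Y - Yhat)^2) / sum(M)``.  Returns a float for numpy
    predictions, a Tensor for Tensor predictions.

    Raises
    ------
    EmptyForegroundError
        If the mask has no foreground voxels (the quantity is undefined; it
        is never silently reported as 0).
    """
    m = _mask_array(mask)
    t = np.asarray(target, dtype=np.float64)
    differentiable = isinstance(prediction, Tensor)
    p = prediction if differentiable else Tensor(np.asarray(prediction, dtype=np.float64))
    if t.shape != p.shape or m.shape != t.shape:
        raise ValidationError(
            f"shape mismatch: target {t.shape}, prediction {p.shape}, mask {m.shape}"
        )
    msum = m.sum()
    if msum == 0:
        raise EmptyForegroundError("mask has no foreground voxels; masked MSE undefined")
    diff = Tensor(t) - p
    out = (diff * diff * m).sum() / msum
    return _loss_output(out, differentiable)


def tunable_sigmoid(x, k: float):
    """Normalized tunable sigmoid ``sigma_k(x) = (x - k x) / (k - 2k|x| + 1)``.

    Odd, bounded, maps [-1, 1] onto [-1, 1] with fixed points at 0 and +-1.
    ``k = 0`` is the identity; ``k -> -1`` approaches a step at 0.

    Raises
    ------
    InvalidParameterError
        If ``|k| >= 1`` (the denominator vanishes inside the domain).
    """
    if not -1.0 < k < 1.0:
        raise InvalidParameterError(
            f"k must be in (-1, 1), got {k} (denominator vanishes on [-1, 1])"
        )
    if isinstance(x, Tensor):
        return (x * (1.0 - k)) / (x.abs() * (-2.0 * k) + (k + 1.0))
    a = np.asarray(x, dtype=np.float64)
    _check_finite(a, "x")
    return (a - k * a) / (k - 2.0 * k * np.abs(a) + 1.0)


def soft_foreground(prediction, config: SpotlightLossConfig, threshold: float | None = None):
    """Differentiable soft-thresholding of a [0, 1] prediction.

    With the default ``"direct"`` policy, sigma_k is applied to the
    (clipped) prediction as-is; on [0, 1] the sigmoid fixes 0 and 1 and, for
    negative k, rises steeply just above zero — so the output is a soft
    foreground map whose transition hugs zero intensity.

    The recentring policies instead place the transition at a point c
    (``"otsu_center"``: the target's Otsu ``threshold``; ``"fixed_half"``:
    0.5): the prediction is mapped affinely onto the sigmoid's [-1, 1]
    domain with scale ``max(c, 1 - c)``, passed through sigma_k, and mapped
    back to [0, 1].  A voxel exactly at the transition maps to 0.5; sharper
    (more negative) k drives the output toward a binary step.
    """
    differentiable = isinstance(prediction, Tensor)
    p = prediction if differentiable else Tensor(np.asarray(prediction, dtype=np.float64))
    if config.center_policy == "direct":
        out = tunable_sigmoid(p.clip(0.0, 1.0), config.sigmoid_k)
    else:
        if config.center_policy == "otsu_center":
            if threshold is None:
                raise ValidationError("otsu_center policy requires the target's threshold")
            c = float(threshold)
        else:
            c = 0.5
        scale = max(max(c, 1.0 - c), 1e-12)
        u = ((p - c) / scale).clip(-1.0, 1.0)
        s = tunable_sigmoid(u, config.sigmoid_k)
        out = (s + 1.0) * 0.5
    return out if differentiable else out.data


def dice_loss(soft_prediction, mask, eps: float = 1e-6):
    """Smoothed Dice loss of a soft [0, 1] prediction against a binary mask.

    ``L = 1 - 2 * sum(sigma * M) / (sum(sigma) + sum(M) + eps)``; in [0, 1].
    """
    if not eps > 0:
        raise InvalidParameterError(f"eps must be > 0, got {eps}")
    m = _mask_array(mask)
    differentiable = isinstance(soft_prediction, Tensor)
    s = (
        soft_prediction
        if differentiable
        else Tensor(np.asarray(soft_prediction, dtype=np.float64))
    )
    if s.shape != m.shape:
        raise ValidationError(f"shape mismatch: soft_prediction {s.shape}, mask {m.shape}")
    inter = (s * m).sum()
    out = 1.0 - (inter * 2.0) / (s.sum() + m.sum() + eps)
    return _loss_output(out, differentiable)


def spotlight_loss(target, prediction, config: SpotlightLossConfig | None = None) -> LossValue:
    """The combined Spotlight objective.

    Derives the foreground mask from the *target* (never the prediction) via
    Otsu thresholding, then returns
    ``lambda * L_mmse + (1 - lambda) * L_dice`` with both components
    recorded.  Gradient flows only through the prediction.

    Both volumes are expected min--max normalized to [0, 1].
    """
    if config is None:
        config = SpotlightLossConfig()
    t = np.asarray(target, dtype=np.float64)
    try:
        thr = otsu_threshold(t)
    except DegenerateHistogramError as e:
        raise DegenerateHistogramError(
            f"target volume is degenerate, cannot derive foreground mask: {e}"
        ) from e
    m = (t >= thr).astype(np.float64)

    differentiable = isinstance(prediction, Tensor)
    mmse = masked_mse(t, prediction, m)
    soft = soft_foreground(prediction, config, thr)
    dice = dice_loss(soft, m, config.dice_eps)

    lam = config.lambda_weight
    if differentiable:
        total = mmse * lam + dice * (1.0 - lam)
        return LossValue(
            value=float(total.data),
            components={"mmse": float(mmse.data), "dice": float(dice.data)},
            tensor=total,
        )
    total = lam * mmse + (1.0 - lam) * dice
    return LossValue(value=float(total), components={"mmse": float(mmse), "dice": float(dice)})
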