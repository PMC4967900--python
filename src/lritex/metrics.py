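"""Signal-to-noise and tumor-to-normal ratio statistics.

SNR of a point-like tracer spot is ``A / sqrt(sigma_bg**2 + A)`` — the
fitted Gaussian amplitude over the quadrature sum of background noise and
the shot noise of the signal itself. The tumor-to-normal ratio (TNR) is
either a plain ratio of mean uptakes, or a combination of per-feature
ratios over a subset of mutually independent texture features, which is the
lever by which texture analysis multiplies the discriminative power of a
beta camera beyond plain intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

COMBINERS = ("sum", "mean", "geometric_mean", "quadrature")


@dataclass
class SNRResult:
    """Fitted spot amplitude, background noise and the derived SNR."""

    amplitude: float
    sigma_bg: float
    snr: float
    center: tuple[float, float]
    width: float
    residual_norm: float
    fit_ok: bool = True


def snr_value(amplitude: float, sigma_bg: float) -> float:
    """``SNR = A / sqrt(sigma_bg**2 + A)``, clipped to 0 for A <= 0."""
    if amplitude <= 0:
        return 0.0
    return float(amplitude / np.sqrt(sigma_bg**2 + amplitude))


def _gaussian2d(coords, amplitude, r0, c0, width, offset):
    r, c = coords
    return (
        amplitude * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2.0 * width**2)) + offset
    ).ravel()


def _window_view(pixels: np.ndarray, window: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = window
    rows, cols = pixels.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"window {window} outside image shape {(rows, cols)}")
    return pixels[r0:r1, c0:c1]


def _windows_disjoint(a, b) -> bool:
    return a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2]


def estimate_snr(
    pixels: np.ndarray,
    signal_window: tuple[int, int, int, int],
    background_window: tuple[int, int, int, int],
) -> SNRResult:
    """Fit an isotropic 2D Gaussian to a background-subtracted spot.

    The background level is the mean of the background window; its
    population SD gives ``sigma_bg``. The fit is initialized at the
    window maximum with a 2-pixel width. A failed fit or non-positive
    amplitude is reported with the SNR computed from the amplitude
    clipped at 0.
    """
    pixels = np.asarray(pixels, dtype=float)
    if not _windows_disjoint(signal_window, background_window):
        raise ValueError("signal and background windows overlap")
    bg = _window_view(pixels, background_window)
    bg_mean = float(bg.mean())
    sigma_bg = float(bg.std(ddof=0))
    sig = _window_view(pixels, signal_window) - bg_mean
    rr, cc = np.mgrid[0 : sig.shape[0], 0 : sig.shape[1]]
    peak = np.unravel_index(np.argmax(sig), sig.shape)
    p0 = (float(sig.max()), float(peak[0]), float(peak[1]), 2.0, 0.0)
    fit_ok = True
    try:
        popt, _ = curve_fit(_gaussian2d, (rr, cc), sig.ravel(), p0=p0, maxfev=5000)
        amplitude, r0, c0, width, _offset = popt
    except RuntimeError:
        fit_ok = False
        amplitude, r0, c0, width = p0[0], p0[1], p0[2], p0[3]
    resid = sig.ravel() - _gaussian2d((rr, cc), amplitude, r0, c0, width, 0.0)
    a = max(float(amplitude), 0.0)
    if a == 0.0:
        fit_ok = False
    return SNRResult(
        amplitude=a,
        sigma_bg=sigma_bg,
        snr=snr_value(a, sigma_bg),
        center=(float(r0) + signal_window[0], float(c0) + signal_window[2]),
        width=abs(float(width)),
        residual_norm=float(np.sqrt((resid**2).mean())),
        fit_ok=fit_ok,
    )


def intensity_tnr(
    cancer_pixels: np.ndarray, normal_pixels: np.ndarray, dark_offset: float = 0.0
) -> float:
    """Ratio of mean uptake, cancer over normal, on raw counts.

    ``dark_offset`` (off by default) is subtracted from both means before
    the ratio, for detectors with a constant dark level.
    """
    cancer_pixels = np.asarray(cancer_pixels, dtype=float)
    normal_pixels = np.asarray(normal_pixels, dtype=float)
    if cancer_pixels.size == 0 or normal_pixels.size == 0:
        raise ValueError("both pixel sets must be nonempty")
    normal_mean = float(normal_pixels.mean()) - dark_offset
    if normal_mean <= 0:
        raise ValueError(f"normal mean after offset subtraction is {normal_mean} <= 0")
    return (float(cancer_pixels.mean()) - dark_offset) / normal_mean


def select_independent_features(
    table: pd.DataFrame,
    feature_columns: list[str],
    threshold: float = 0.95,
) -> list[str]:
    """Greedy forward selection of mutually independent features.

    Scanning features in their frozen order, keep a feature iff its absolute
    Pearson correlation (across ROIs) with every already-kept feature is
    below ``threshold``. Constant features are skipped with a warning.
    """
    if len(table) < 3:
        raise ValueError("independence screening needs at least 3 ROIs")
    kept: list[str] = []
    for name in feature_columns:
        x = table[name].to_numpy(dtype=float)
        if x.std(ddof=0) == 0:
            warnings.warn(f"feature {name!r} is constant across ROIs; skipped")
            continue
        ok = True
        for other in kept:
            r = np.corrcoef(x, table[other].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


@dataclass
class TNRResult:
    """Per-feature oriented ratios and their combination."""

    per_feature: dict[str, float]
    independent_features: list[str]
    combiner: str
    combined: float
    combined_by: dict[str, float] = field(default_factory=dict)


def _combine(ratios: np.ndarray, combiner: str) -> float:
    if combiner == "sum":
        return float(ratios.sum())
    if combiner == "mean":
        return float(ratios.mean())
    if combiner == "geometric_mean":
        return float(np.exp(np.log(ratios).mean()))
    if combiner == "quadrature":
        return float(np.sqrt((ratios**2).sum()))
    raise ValueError(f"unknown combiner {combiner!r}")


def combined_feature_tnr(
    table: pd.DataFrame,
    labels,
    independent_features: list[str],
    combiner: str = "sum",
) -> TNRResult:
    """Combine per-feature cancer/normal mean ratios over independent features.

    Features with non-positive values are shifted (min-shift + 1) before the
    ratio; each ratio is oriented as ``max(r, 1/r)`` so features where
    normal tissue scores higher still contribute discrimination. The
    default combiner is the sum over independent features; all combiners
    are reported side by side in ``combined_by``.
    """
    if not independent_features:
        raise ValueError("independent feature set is empty")
    labels = np.asarray(labels)
    cancer = labels == "cancer"
    normal = labels == "normal"
    if not cancer.any() or not normal.any():
        raise ValueError("both label groups must be nonempty")
    per_feature: dict[str, float] = {}
    for name in independent_features:
        x = table[name].to_numpy(dtype=float)
        lo = x.min()
        if lo <= 0:
            x = x + (1.0 - lo)
        r = x[cancer].mean() / x[normal].mean()
        per_feature[name] = float(max(r, 1.0 / r))
    ratios = np.array(list(per_feature.values()))
    return TNRResult(
        per_feature=per_feature,
        independent_features=list(independent_features),
        combiner=combiner,
        combined=_combine(ratios, combiner),
        combined_by={c: _combine(ratios, c) for c in COMBINERS},
    )
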