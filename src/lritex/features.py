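"""Gray-level texture features for radioluminescence ROIs.

Implements the radiomics-style feature set used to discriminate tumor from
normal tissue in low-count beta-camera images:

* min/max-relative resampling of raw counts onto ``2**s`` discrete gray
  levels (32 by default),
* the gray-level co-occurrence matrix (GLCM) averaged over the four
  distance-1 directions, with three Haralick features (angular second
  moment, correlation, contrast),
* the gray-level run-length matrix (GLRLM) in four directions with the
  eleven classical run-length features (SRE, LRE, GLN, RLN, RP, LGRE,
  HGRE, SRLGE, SRHGE, LRLGE, LRHGE), averaged across directions,
* the neighborhood gray-tone difference matrix (NGTDM) with the
  Amadasun–King contrast feature (and, optionally, coarseness),
* six global pixel statistics on the raw (un-resampled) counts.

Under the default configuration a ROI yields exactly 21 named features in
the frozen order :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Distance-1 offsets (drow, dcol) for the 0, 45, 90 and 135 degree
#: co-occurrence directions, image rows increasing downwards.
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Run directions in degrees: 0 = along rows, 90 = along columns,
#: 45 = up-right anti-diagonals, 135 = down-right diagonals.
RLM_DIRECTIONS: tuple[int, ...] = (0, 45, 90, 135)

GLOBAL_FEATURE_NAMES = (
    "intensity_max",
    "intensity_min",
    "intensity_mean",
    "intensity_sd",
    "skewness",
    "kurtosis",
)
GLCM_FEATURE_NAMES = ("angular_second_moment", "correlation", "contrast_glcm")
GLRLM_FEATURE_NAMES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)
NGTDM_FEATURE_NAMES = ("ngtdm_contrast",)

#: Frozen order of the 21 default features; CSV feature tables use exactly
#: this header so runs stay comparable.
FEATURE_NAMES: tuple[str, ...] = (
    GLOBAL_FEATURE_NAMES + GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES + NGTDM_FEATURE_NAMES
)

#: Optional extra features enabled through :class:`FeatureConfig`.
OPTIONAL_FEATURE_NAMES: tuple[str, ...] = ("ngtdm_coarseness",)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    Parameters
    ----------
    s_bits:
        Resampling depth; gray levels live in ``1..2**s_bits``. Default 5
        (32 levels).
    ngtdm_d:
        NGTDM neighborhood half-width; the neighborhood is the
        ``(2d+1) x (2d+1)`` square minus its center. Default 1.
    include_coarseness:
        Append the NGTDM coarseness feature as a 22nd column. Off by
        default (the default vector has exactly 21 entries).
    """

    s_bits: int = 5
    ngtdm_d: int = 1
    include_coarseness: bool = False

    @property
    def feature_names(self) -> tuple[str, ...]:
        if self.include_coarseness:
            return FEATURE_NAMES + OPTIONAL_FEATURE_NAMES
        return FEATURE_NAMES


@dataclass(frozen=True)
class GrayLevelROI:
    """ROI resampled onto discrete gray levels ``1..2**s_bits``."""

    levels: np.ndarray
    s_bits: int
    original_min: float
    original_max: float

    @property
    def n_levels(self) -> int:
        return 2 ** self.s_bits


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric, normalized GLCM averaged over the four distance-1 offsets."""

    p: np.ndarray
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS


@dataclass(frozen=True)
class RunLengthMatrix:
    """Per-direction run counts ``r[direction][i-1, j-1]`` for gray level i, run length j."""

    matrices: dict[int, np.ndarray]
    n_pixels: int


@dataclass(frozen=True)
class NGTDMVector:
    """Neighborhood gray-tone difference vector and its bookkeeping.

    ``s[i-1]`` sums |tone - neighborhood mean| over valid (non-border)
    pixels of tone i; ``counts[i-1]`` is the number of valid pixels of tone
    i, and ``n = (width - 2d)(height - 2d)`` is the total number of valid
    pixels, so ``p_i = counts/n``.
    """

    s: np.ndarray
    counts: np.ndarray
    n: int
    d: int
    n_gray_tones: int  # N_g: tones present among valid pixels
    max_gray_tone: int  # G_h: largest tone anywhere in the ROI

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n


def resample_gray_levels(pixels: np.ndarray, s_bits: int = 5) -> GrayLevelROI:
    """Map raw ROI intensities onto gray levels ``1..2**s_bits``.

    ``P(x) = floor(2**s * (I(x) - min) / (max - min + 1)) + 1`` with min/max
    taken over the ROI, so the mapping is shift-invariant in intensity and a
    constant ROI collapses to level 1.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("ROI is empty")
    vmin = pixels.min()
    vmax = pixels.max()
    span = vmax - vmin + 1.0
    levels = np.floor((2**s_bits) * (pixels - vmin) / span).astype(np.int64) + 1
    return GrayLevelROI(levels=levels, s_bits=s_bits, original_min=vmin, original_max=vmax)


def _directed_pair_counts(levels: np.ndarray, drow: int, dcol: int, n_levels: int) -> np.ndarray:
    """Counts of ordered gray-level pairs at offset (drow, dcol)."""
    rows, cols = levels.shape
    r0, r1 = max(0, -drow), rows - max(0, drow)
    c0, c1 = max(0, -dcol), cols - max(0, dcol)
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol]
    idx = (src.ravel() - 1) * n_levels + (dst.ravel() - 1)
    return np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels).astype(float)


def cooccurrence_matrix(gl: GrayLevelROI) -> CooccurrenceMatrix:
    """Four-direction average of symmetrized, normalized co-occurrence matrices.

    For each distance-1 offset the ordered pair counts are accumulated
    together with their transpose (equivalently: the opposite offset) before
    normalization, then the four normalized matrices are averaged.
    """
    levels = gl.levels
    if levels.ndim != 2 or min(levels.shape) < 2:
        raise ValueError(f"ROI too small for co-occurrence offsets: shape {levels.shape}")
    L = gl.n_levels
    acc = np.zeros((L, L))
    for drow, dcol in GLCM_OFFSETS:
        counts = _directed_pair_counts(levels, drow, dcol, L)
        counts = counts + counts.T
        total = counts.sum()
        if total == 0:
            raise ValueError(f"no pixel pairs at offset ({drow}, {dcol})")
        acc += counts / total
    return CooccurrenceMatrix(p=acc / len(GLCM_OFFSETS))


def glcm_features(m1: CooccurrenceMatrix | np.ndarray) -> dict[str, float]:
    """Angular second moment, correlation and contrast of a normalized GLCM.

    Correlation is defined as 0 when either marginal standard deviation
    vanishes (e.g. a constant ROI), keeping feature tables finite.
    """
    p = m1.p if isinstance(m1, CooccurrenceMatrix) else np.asarray(m1, dtype=float)
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"co-occurrence matrix is not normalized (sum = {total!r})")
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    asm = float((p**2).sum())
    contrast = float(((i[:, None] - i[None, :]) ** 2 * p).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((i * pj).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    var_j = float(((i - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        cov = float(((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum())
        corr = cov / np.sqrt(var_i * var_j)
    return {"angular_second_moment": asm, "correlation": corr, "contrast_glcm": contrast}


def _direction_lines(levels: np.ndarray, direction: int) -> list[np.ndarray]:
    rows, cols = levels.shape
    if direction == 0:
        return [levels[r, :] for r in range(rows)]
    if direction == 90:
        return [levels[:, c] for c in range(cols)]
    if direction == 45:
        flipped = np.fliplr(levels)
        return [np.diagonal(flipped, k) for k in range(-(rows - 1), cols)]
    if direction == 135:
        return [np.diagonal(levels, k) for k in range(-(rows - 1), cols)]
    raise ValueError(f"unknown run direction {direction}")


def run_length_matrices(gl: GrayLevelROI) -> RunLengthMatrix:
    """Maximal-run decomposition of the ROI along all four directions.

    Satisfies the pixel-conservation invariant
    ``sum_ij j * r[i, j] == n_pixels`` per direction.
    """
    levels = gl.levels
    if levels.size == 0:
        raise ValueError("ROI is empty")
    L = gl.n_levels
    max_len = max(levels.shape)
    matrices: dict[int, np.ndarray] = {}
    for direction in RLM_DIRECTIONS:
        r = np.zeros((L, max_len))
        for line in _direction_lines(levels, direction):
            line = np.asarray(line)
            if line.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(line)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [line.size]))
            run_levels = line[starts]
            run_lengths = ends - starts
            np.add.at(r, (run_levels - 1, run_lengths - 1), 1)
        matrices[direction] = r
    return RunLengthMatrix(matrices=matrices, n_pixels=int(levels.size))


def _run_length_features_single(r: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    i2 = np.arange(1, r.shape[0] + 1, dtype=float)[:, None] ** 2
    j2 = np.arange(1, r.shape[1] + 1, dtype=float)[None, :] ** 2
    return {
        "sre": float((r / j2).sum() / n_runs),
        "lre": float((r * j2).sum() / n_runs),
        "gln": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "rln": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "rp": float(n_runs / n_pixels),
        "lgre": float((r / i2).sum() / n_runs),
        "hgre": float((r * i2).sum() / n_runs),
        "srlge": float((r / (i2 * j2)).sum() / n_runs),
        "srhge": float((r * i2 / j2).sum() / n_runs),
        "lrlge": float((r * j2 / i2).sum() / n_runs),
        "lrhge": float((r * i2 * j2).sum() / n_runs),
    }


def glrlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """Eleven classical run-length features, averaged over the 4 directions.

    Run percentage (RP) uses the total ROI pixel count as denominator.
    """
    per_direction = [
        _run_length_features_single(rlm.matrices[d], rlm.n_pixels) for d in RLM_DIRECTIONS
    ]
    return {
        name: float(np.mean([f[name] for f in per_direction])) for name in GLRLM_FEATURE_NAMES
    }


def ngtdm(gl: GrayLevelROI, d: int = 1) -> NGTDMVector:
    """Neighborhood gray-tone difference vector.

    For every non-border pixel of tone ``i`` accumulate
    ``|i - mean(neighbors)|`` where the neighborhood is the centered
    ``(2d+1) x (2d+1)`` square excluding the pixel itself; border pixels
    within ``d`` of the ROI edge are excluded from both the sums and the
    tone probabilities.
    """
    levels = gl.levels
    win = 2 * d + 1
    if levels.shape[0] < win or levels.shape[1] < win:
        raise ValueError(
            f"ROI shape {levels.shape} too small for NGTDM neighborhood {win}x{win}"
        )
    L = gl.n_levels
    windows = sliding_window_view(levels.astype(float), (win, win))
    center = levels[d:-d, d:-d].astype(float)
    nbr_mean = (windows.sum(axis=(2, 3)) - center) / (win * win - 1)
    diff = np.abs(center - nbr_mean)
    tones = levels[d:-d, d:-d].ravel() - 1
    s = np.bincount(tones, weights=diff.ravel(), minlength=L)
    counts = np.bincount(tones, minlength=L)
    n = center.size
    return NGTDMVector(
        s=s,
        counts=counts,
        n=int(n),
        d=d,
        n_gray_tones=int((counts > 0).sum()),
        max_gray_tone=int(levels.max()),
    )


def ngtdm_contrast(v: NGTDMVector) -> float:
    """Amadasun–King contrast from an NGTDM vector.

    ``f_con = [1/(N_g (N_g - 1)) * sum_ij p_i p_j (i - j)^2] * [1/n * sum_i s(i)]``
    over tones present among valid pixels; defined as 0 when fewer than two
    tones are present (constant ROI).
    """
    ng = v.n_gray_tones
    if ng < 2:
        return 0.0
    present = np.flatnonzero(v.counts)
    tones = (present + 1).astype(float)
    p = v.p[present]
    spread = float((p[:, None] * p[None, :] * (tones[:, None] - tones[None, :]) ** 2).sum())
    return spread / (ng * (ng - 1)) * float(v.s.sum()) / v.n


def ngtdm_coarseness(v: NGTDMVector, eps: float = 1e-12) -> float:
    """Amadasun–King coarseness, ``1 / (eps + sum_i p_i s(i))``."""
    return float(1.0 / (eps + float((v.p * v.s).sum())))


def global_stats(pixels: np.ndarray) -> dict[str, float]:
    """Global pixel statistics of the raw (un-resampled) ROI.

    Moment-based with population normalization; kurtosis is non-excess
    (Gaussian -> 3); skewness and kurtosis are defined as 0 for a constant
    ROI.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("ROI is empty")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd > 0:
        centered = x - mean
        skew = float((centered**3).mean() / sd**3)
        kurt = float((centered**4).mean() / sd**4)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "intensity_max": float(x.max()),
        "intensity_min": float(x.min()),
        "intensity_mean": mean,
        "intensity_sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
    }


def feature_vector(pixels: np.ndarray, config: FeatureConfig | None = None) -> dict[str, float]:
    """Full named feature vector of a ROI in the frozen feature order.

    Returns 21 features by default (6 global + 3 GLCM + 11 GLRLM + 1 NGTDM);
    ``config.include_coarseness`` appends a 22nd NGTDM feature.
    """
    config = config or FeatureConfig()
    gl = resample_gray_levels(pixels, config.s_bits)
    out = global_stats(pixels)
    out.update(glcm_features(cooccurrence_matrix(gl)))
    out.update(glrlm_features(run_length_matrices(gl)))
    v = ngtdm(gl, config.ngtdm_d)
    out["ngtdm_contrast"] = ngtdm_contrast(v)
    if config.include_coarseness:
        out["ngtdm_coarseness"] = ngtdm_coarseness(v)
    return {name: out[name] for name in config.feature_names}
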