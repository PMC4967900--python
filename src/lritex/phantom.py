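"""Synthetic radioluminescence scene generator.

Forward model for a lensless beta-camera frame: each tissue region emits
photons at a mean rate (photons/pixel/second) modulated by a spatial
texture field, the expected photon map is integrated over the acquisition
time, and a generic EMCCD detector model converts expected photons into
16-bit counts via Poisson shot noise, a multiplicative gain, additive
Gaussian read noise and a constant dark offset.

Two texture families are provided:

* ``smooth`` — Gaussian-filtered white noise with a stated correlation
  length, scaled to a coefficient of variation; emulates the relative
  uniformity of benign tissue.
* ``heterogeneous`` — a multiplicative lognormal field (pointwise
  ``exp(sigma * G)`` with correlated standard-normal ``G``) plus optional
  bright Gaussian blobs; emulates the patchy, high-variance uptake of
  tumor tissue.

An optional bright rim along the tissue-mask boundary emulates tracer
accumulation at drying tissue edges — the artifact that produces
false-positive edge ROIs in the classification workflow.

Everything is deterministic given the spec seed: identical specs produce
bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import DEFAULT_PIXEL_SIZE_MM, Image

#: Default detector raster: 300 rows x 407 columns (4.80 x 6.51 mm at 16 um).
DEFAULT_DETECTOR_SHAPE = (300, 407)

#: Default placement of the two tissue slices on the detector:
#: half-open (row0, row1, col0, col1) rectangles, 260 x 120 px each, which
#: exactly carry a 13 x 6 grid of 20 x 20 px ROIs per sample.
DEFAULT_NORMAL_RECT = (20, 280, 40, 160)
DEFAULT_CANCER_RECT = (20, 280, 247, 367)

#: Printed mean-uptake ratio between the cancer and normal slice (490/300).
DEFAULT_CANCER_RATIO = 490.0 / 300.0


@dataclass(frozen=True)
class SmoothTexture:
    """Gaussian-filtered noise texture: field = 1 + cv * G, G unit-variance."""

    correlation_length_px: float = 4.0
    cv: float = 0.10


@dataclass(frozen=True)
class HeterogeneousTexture:
    """Multiplicative lognormal texture plus optional bright blobs.

    The field is ``exp(log_sd * G)`` with correlated unit-variance Gaussian
    ``G`` (pointwise mean ``exp(log_sd**2 / 2)``), plus Gaussian bumps of
    amplitude ``blob_amplitude`` at a Poisson density of ``blob_density``
    blobs per pixel.
    """

    correlation_length_px: float = 3.0
    log_sd: float = 0.5
    blob_density: float = 0.0
    blob_amplitude: float = 1.0
    blob_sigma_px: float = 3.0

    @property
    def mean_field(self) -> float:
        """Analytic expectation of the texture field (edge effects ignored)."""
        blob_mean = self.blob_density * self.blob_amplitude * 2.0 * np.pi * self.blob_sigma_px**2
        return float(np.exp(self.log_sd**2 / 2.0) + blob_mean)


@dataclass(frozen=True)
class EdgeRim:
    """Bright band of ``width_px`` inside the mask boundary, rate x multiplier."""

    width_px: int = 6
    rim_multiplier: float = 3.0


@dataclass(frozen=True)
class TissueRegion:
    """One emitting region: a rectangle or polygon mask with a mean rate and texture.

    ``mask`` is either a half-open rectangle ``(row0, row1, col0, col1)`` or
    an ``(N, 2)`` array of polygon vertices in (row, col) pixel coordinates.
    """

    mask: tuple[int, int, int, int] | np.ndarray
    label: str
    mean_rate: float  # expected photons / pixel / second
    texture: SmoothTexture | HeterogeneousTexture | None = None
    edge_rim: EdgeRim | None = None

    def mask_array(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        if isinstance(self.mask, tuple) and len(self.mask) == 4:
            r0, r1, c0, c1 = self.mask
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1] or r1 <= r0 or c1 <= c0:
                raise ValueError(
                    f"region {self.label!r}: rectangle {self.mask} outside detector {shape}"
                )
            out[r0:r1, c0:c1] = True
        else:
            from skimage.draw import polygon

            verts = np.asarray(self.mask, dtype=float)
            if verts.min() < 0 or verts[:, 0].max() > shape[0] or verts[:, 1].max() > shape[1]:
                raise ValueError(f"region {self.label!r}: polygon outside detector {shape}")
            rr, cc = polygon(verts[:, 0], verts[:, 1], shape)
            out[rr, cc] = True
        return out


@dataclass(frozen=True)
class PointSourceSpec:
    """In-silico analogue of a dried radiotracer spot / pocket point source."""

    center: tuple[float, float]  # (row, col) pixels
    total_rate: float  # photons / second integrated over the spot
    psf_sigma: float = 3.0  # pixels

    def __post_init__(self) -> None:
        if self.total_rate < 0:
            raise ValueError("total_rate must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of a simulated radioluminescence frame."""

    detector_shape: tuple[int, int] = DEFAULT_DETECTOR_SHAPE
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    regions: tuple[TissueRegion, ...] = ()
    acquisition_time: float = 60.0  # seconds
    gain: float = 1.0
    read_noise_sd: float = 10.0  # counts
    offset: float = 100.0  # counts (dark level)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.detector_shape) < 1:
            raise ValueError("detector_shape must be strictly positive")
        if self.acquisition_time < 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ValueError("acquisition_time, read_noise_sd and offset must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        for region in self.regions:
            if region.mean_rate < 0:
                raise ValueError(f"region {region.label!r}: mean_rate must be >= 0")
            if region.edge_rim is not None and region.edge_rim.width_px < 0:
                raise ValueError(f"region {region.label!r}: rim width must be >= 0")


def _gaussian_filter_norm(sigma: float) -> float:
    """Pointwise SD of unit white noise after Gaussian filtering.

    Equals the L2 norm of the filter kernel; computed by filtering a
    delta so truncation matches scipy's implementation exactly.
    """
    half = int(4 * sigma + 0.5) + 1
    delta = np.zeros((2 * half + 1, 2 * half + 1))
    delta[half, half] = 1.0
    kernel = ndimage.gaussian_filter(delta, sigma, mode="constant")
    return float(np.sqrt((kernel**2).sum()))


def _correlated_unit_noise(shape, correlation_length_px, rng) -> np.ndarray:
    """Gaussian-filtered white noise with unit pointwise marginal variance.

    Normalized by the exact filter norm (not the sample SD, which is
    biased low on patches smaller than a few hundred correlation areas),
    so the pointwise marginal is N(0, 1) away from the boundary.
    """
    g = rng.standard_normal(shape)
    if correlation_length_px > 0:
        g = ndimage.gaussian_filter(g, correlation_length_px, mode="reflect")
        g = g / _gaussian_filter_norm(correlation_length_px)
    return g


def _texture_field(shape, texture, rng) -> np.ndarray:
    if texture is None:
        return np.ones(shape)
    if isinstance(texture, SmoothTexture):
        g = _correlated_unit_noise(shape, texture.correlation_length_px, rng)
        return np.clip(1.0 + texture.cv * g, 0.0, None)
    if isinstance(texture, HeterogeneousTexture):
        g = _correlated_unit_noise(shape, texture.correlation_length_px, rng)
        fld = np.exp(texture.log_sd * g)
        if texture.blob_density > 0:
            n_blobs = rng.poisson(texture.blob_density * shape[0] * shape[1])
            if n_blobs > 0:
                rows = rng.uniform(0, shape[0], n_blobs)
                cols = rng.uniform(0, shape[1], n_blobs)
                rr = np.arange(shape[0])[:, None]
                cc = np.arange(shape[1])[None, :]
                for r0, c0 in zip(rows, cols):
                    fld += texture.blob_amplitude * np.exp(
                        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * texture.blob_sigma_px**2)
                    )
        return fld
    raise TypeError(f"unknown texture model {type(texture).__name__}")


def generate_activity_map(spec: PhantomSpec) -> np.ndarray:
    """Expected photon counts per pixel over the acquisition time.

    Deterministic given the spec (texture fields are drawn from
    ``spec.seed``); background pixels are exactly 0 before the detector
    offset is added.
    """
    shape = spec.detector_shape
    masks = [region.mask_array(shape) for region in spec.regions]
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if np.any(masks[a] & masks[b]):
                raise ValueError(
                    f"regions {spec.regions[a].label!r} and {spec.regions[b].label!r} overlap"
                )
    expected = np.zeros(shape)
    for idx, (region, mask) in enumerate(zip(spec.regions, masks)):
        rng = np.random.default_rng([spec.seed, 7, idx])
        fld = _texture_field(shape, region.texture, rng)
        if region.edge_rim is not None and region.edge_rim.width_px > 0:
            eroded = ndimage.binary_erosion(mask, iterations=region.edge_rim.width_px)
            band = mask & ~eroded
            fld = fld.copy()
            fld[band] *= region.edge_rim.rim_multiplier
        expected[mask] += spec.acquisition_time * region.mean_rate * fld[mask]
    return expected


def apply_detector_model(expected: np.ndarray, spec: PhantomSpec) -> Image:
    """Convert an expected-photon map into integer detector counts.

    ``counts = clip(round(gain * Poisson(expected) + N(0, read_noise) + offset), 0, 65535)``,
    reproducible from ``spec.seed``.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.size and expected.min() < 0:
        raise ValueError("expected photon counts must be >= 0 everywhere")
    rng = np.random.default_rng([spec.seed, 13])
    out = spec.gain * rng.poisson(expected).astype(float)
    if spec.read_noise_sd > 0:
        out += rng.normal(0.0, spec.read_noise_sd, size=expected.shape)
    out += spec.offset
    counts = np.clip(np.rint(out), 0, 65535).astype(np.uint16)
    return Image(
        pixels=counts,
        pixel_size_mm=spec.pixel_size_mm,
        acquisition_time_s=spec.acquisition_time,
    )


def two_tissue_spec(
    normal_rate: float = 5.0,
    cancer_ratio: float = DEFAULT_CANCER_RATIO,
    heterogeneity: float = 0.5,
    rim_on: bool = False,
    seed: int = 0,
    acquisition_time: float = 60.0,
    gain: float = 1.0,
    read_noise_sd: float = 10.0,
    offset: float = 100.0,
    normal_cv: float = 0.10,
    blob_density: float = 3e-4,
    rim: EdgeRim = EdgeRim(),
    detector_shape: tuple[int, int] = DEFAULT_DETECTOR_SHAPE,
    normal_rect: tuple[int, int, int, int] = DEFAULT_NORMAL_RECT,
    cancer_rect: tuple[int, int, int, int] = DEFAULT_CANCER_RECT,
) -> PhantomSpec:
    """PhantomSpec for two adjacent tissue slices: smooth normal (left) and
    heterogeneous cancer (right) with mean counts in ratio ``cancer_ratio``.

    The cancer region rate is divided by the analytic mean of its texture
    field so the realized region means sit at ``normal_rate`` and
    ``normal_rate * cancer_ratio`` photons/pixel/second.
    """
    if cancer_ratio < 1:
        raise ValueError("cancer_ratio must be >= 1")
    cancer_texture = HeterogeneousTexture(log_sd=heterogeneity, blob_density=blob_density)
    regions = (
        TissueRegion(
            mask=normal_rect,
            label="normal",
            mean_rate=normal_rate,
            texture=SmoothTexture(cv=normal_cv),
            edge_rim=rim if rim_on else None,
        ),
        TissueRegion(
            mask=cancer_rect,
            label="cancer",
            mean_rate=normal_rate * cancer_ratio / cancer_texture.mean_field,
            texture=cancer_texture,
            edge_rim=rim if rim_on else None,
        ),
    )
    return PhantomSpec(
        detector_shape=detector_shape,
        regions=regions,
        acquisition_time=acquisition_time,
        gain=gain,
        read_noise_sd=read_noise_sd,
        offset=offset,
        seed=seed,
    )


def generate_two_tissue_scene(
    normal_rate: float = 5.0,
    cancer_ratio: float = DEFAULT_CANCER_RATIO,
    heterogeneity: float = 0.5,
    rim_on: bool = False,
    seed: int = 0,
    **kwargs,
) -> tuple[Image, np.ndarray]:
    """Simulate the two-slice benchmark frame with its ground-truth mask.

    Returns the detector frame and a per-pixel uint8 label mask
    (0 background, 1 normal, 2 cancer).
    """
    spec = two_tissue_spec(
        normal_rate=normal_rate,
        cancer_ratio=cancer_ratio,
        heterogeneity=heterogeneity,
        rim_on=rim_on,
        seed=seed,
        **kwargs,
    )
    image = apply_detector_model(generate_activity_map(spec), spec)
    labels = np.zeros(spec.detector_shape, dtype=np.uint8)
    code = {"normal": 1, "cancer": 2}
    for region in spec.regions:
        labels[region.mask_array(spec.detector_shape)] = code.get(region.label, 0)
    return image, labels


def generate_point_source_frame(source: PointSourceSpec, spec: PhantomSpec) -> Image:
    """Frame of a Gaussian point spot added on top of the phantom background."""
    rows, cols = spec.detector_shape
    r0, c0 = source.center
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"point source center {source.center} outside frame {(rows, cols)}")
    expected = generate_activity_map(spec)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    norm = source.total_rate * spec.acquisition_time / (2.0 * np.pi * source.psf_sigma**2)
    expected = expected + norm * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * source.psf_sigma**2)
    )
    return apply_detector_model(expected, spec)
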