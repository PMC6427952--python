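"""Stimulus generation and preprocessing for the LGN-V1 model.

Covers the retina-like preprocessing front end (zero-phase whitening /
low-pass filters), synthetic naturalistic image ensembles (Gaussian images
with 1/f amplitude spectra), patch sampling, the split of signed pixel
intensities into non-negative ON and OFF channels, and circular sinusoidal
grating probes used for orientation tuning.

Conventions
-----------
* Images and patches are square 2-D arrays indexed ``[row, col]``; the
  geometric x axis is the column index and y the row index.
* Patches are flattened row-major, so LGN cell ``i`` of either polarity
  sees pixel ``(i // P, i % P)`` for patch size ``P``.
* Filter cutoffs are expressed in cycles per image at a reference image
  size and rescaled proportionally when a filter is built for another
  size, keeping cycles-per-pixel fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterSpec",
    "ImageEnsemble",
    "OnOffStimulus",
    "GratingSpec",
    "ORIENTATION_GRID",
    "PHASE_GRID",
    "CONTRAST_GRID",
    "SPATIAL_FREQUENCY_GRID",
    "build_filter",
    "apply_zero_phase_filter",
    "load_image_ensemble",
    "generate_pink_noise_ensemble",
    "make_whitened_ensemble",
    "white_noise_patches",
    "sample_patches",
    "encode_on_off",
    "encode_batch",
    "generate_grating",
    "grating_grid",
]

#: Orientation search grid, degrees (0 to 175 in steps of 5).
ORIENTATION_GRID = np.arange(0.0, 180.0, 5.0)
#: Phase grid for drifting gratings, degrees (0 to 330 in steps of 30).
PHASE_GRID = np.arange(0.0, 360.0, 30.0)
#: Contrast levels (grating amplitude), 0.2 to 1.0 in steps of 0.2.
CONTRAST_GRID = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
#: Spatial frequency grid, cycles/pixel (0.05 to 0.3 in steps of 0.05).
SPATIAL_FREQUENCY_GRID = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30])


@dataclass(frozen=True)
class FilterSpec:
    """Radially symmetric zero-phase amplitude filter.

    Parameters
    ----------
    kind : {"whitening", "lowpass"}
        ``"whitening"`` is the retina-like filter with amplitude response
        ``R(f) = f * exp(-(f / cutoff)**4)``; ``"lowpass"`` drops the
        leading ``f`` and has response ``L(f) = exp(-(f / cutoff)**4)``.
    cutoff : float
        Cutoff spatial frequency in cycles per image at ``image_size``.
    image_size : int
        Reference image side length (pixels) at which ``cutoff`` is
        quoted.  Building the filter at another size rescales the cutoff
        proportionally so cycles-per-pixel are preserved.
    """

    kind: str
    cutoff: float
    image_size: int = 512

    def __post_init__(self) -> None:
        if self.kind not in ("whitening", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("filter cutoff must be positive")
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")


@dataclass
class ImageEnsemble:
    """Stack of same-size grayscale images in whitened-intensity units."""

    images: np.ndarray  # (n_images, size, size)
    provenance: str = "file"
    variance_target: float | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a stack of square arrays")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def size(self) -> int:
        return self.images.shape[1]

    def variance(self) -> float:
        """Pixel variance pooled over the whole ensemble."""
        return float(self.images.var())

    def scaled_to_variance(self, target: float) -> "ImageEnsemble":
        """Rescale by one global scalar so the pooled variance equals ``target``."""
        v = self.variance()
        if v == 0:
            raise ValueError("cannot scale a constant ensemble to a target variance")
        out = self.images * np.sqrt(target / v)
        return ImageEnsemble(out, provenance=self.provenance, variance_target=target)


@dataclass
class OnOffStimulus:
    """A patch encoded as complementary non-negative ON and OFF vectors.

    For each pixel at most one of the two channels is nonzero: a positive
    intensity drives the ON cell, a negative one drives the OFF cell with
    its absolute value.  ``x`` is the concatenation ``[x_on, x_off]``.
    """

    x_on: np.ndarray
    x_off: np.ndarray
    patch_shape: tuple[int, int] = (16, 16)

    @property
    def x(self) -> np.ndarray:
        return np.concatenate([self.x_on, self.x_off])

    def to_patch(self) -> np.ndarray:
        """Reconstruct the signed patch as ``x_on - x_off``."""
        return (self.x_on - self.x_off).reshape(self.patch_shape)


@dataclass(frozen=True)
class GratingSpec:
    """Circular-aperture sinusoidal grating probe."""

    radius: float
    spatial_frequency: float  # cycles/pixel
    orientation: float  # degrees in [0, 180)
    phase: float = 0.0  # degrees
    contrast: float = 1.0  # sinusoid amplitude
    patch_size: int = 16


def radial_frequency_grid(size: int) -> np.ndarray:
    """2-D grid of radial spatial frequencies in cycles per image."""
    f1 = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(f1, f1, indexing="xy")
    return np.hypot(fx, fy)


def build_filter(spec: FilterSpec, size: int | None = None) -> np.ndarray:
    """Evaluate the amplitude response of ``spec`` on the 2-D FFT grid.

    Parameters
    ----------
    spec : FilterSpec
    size : int, optional
        Side length at which to build the filter; defaults to
        ``spec.image_size``.  The cutoff is rescaled by
        ``size / spec.image_size``.

    Returns
    -------
    ndarray of shape (size, size)
        Amplitude response in the standard two-sided FFT layout.  The DC
        bin is exactly 0 for the whitening filter and exactly 1 for the
        low-pass filter.
    """
    if size is None:
        size = spec.image_size
    if size < 2:
        raise ValueError("filter size must be >= 2")
    cutoff = spec.cutoff * size / spec.image_size
    f = radial_frequency_grid(size)
    envelope = np.exp(-((f / cutoff) ** 4))
    if spec.kind == "whitening":
        return f * envelope
    return envelope


def apply_zero_phase_filter(
    images: np.ndarray | ImageEnsemble, amplitude: np.ndarray
) -> np.ndarray | ImageEnsemble:
    """Multiply each image's Fourier amplitude by ``amplitude``, phase untouched.

    Accepts a single image, a stack, or an :class:`ImageEnsemble` (in
    which case an ensemble is returned).  The filter must have been built
    at the image size.
    """
    if isinstance(images, ImageEnsemble):
        out = apply_zero_phase_filter(images.images, amplitude)
        return ImageEnsemble(
            out, provenance=images.provenance, variance_target=images.variance_target
        )
    arr = np.asarray(images, dtype=float)
    if arr.shape[-2:] != amplitude.shape:
        raise ValueError(
            f"filter built for size {amplitude.shape}, images have {arr.shape[-2:]}"
        )
    spectrum = np.fft.fft2(arr, axes=(-2, -1))
    filtered = np.fft.ifft2(spectrum * amplitude, axes=(-2, -1)).real
    return filtered


def load_image_ensemble(paths, variance_target: float | None = None) -> ImageEnsemble:
    """Load grayscale images from files into an :class:`ImageEnsemble`.

    Accepts a path or list of paths; ``.npy``/``.npz`` arrays (a single
    stack or one image per file) and lossless rasters (PGM/PNG/TIFF, read
    via Pillow and converted to grayscale) are supported.  When
    ``variance_target`` is given the pooled variance is rescaled to it.
    """
    from pathlib import Path

    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    images = []
    for p in paths:
        p = Path(p)
        if p.suffix == ".npy":
            arr = np.load(p)
            images.extend(arr if arr.ndim == 3 else [arr])
        elif p.suffix == ".npz":
            with np.load(p) as data:
                for key in data.files:
                    arr = data[key]
                    images.extend(arr if arr.ndim == 3 else [arr])
        else:
            from PIL import Image

            images.append(np.asarray(Image.open(p).convert("F"), dtype=float))
    ensemble = ImageEnsemble(np.stack(images), provenance="file")
    if variance_target is not None:
        ensemble = ensemble.scaled_to_variance(variance_target)
    return ensemble


def generate_pink_noise_ensemble(
    n_images: int, size: int, seed: int | np.random.Generator
) -> ImageEnsemble:
    """Gaussian random images with amplitude spectrum proportional to 1/f.

    These emulate the second-order statistics of natural scenes (pink
    noise) and serve as the synthetic training ensemble: white Gaussian
    fields are shaped in the Fourier domain by 1/f, which leaves phases
    random and marginals Gaussian.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_images, size, size))
    f = radial_frequency_grid(size)
    with np.errstate(divide="ignore"):
        shaping = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), 0.0)
    images = apply_zero_phase_filter(white, shaping)
    return ImageEnsemble(images, provenance="synthetic-pink-noise")


def make_whitened_ensemble(
    n_images: int,
    size: int,
    seed: int | np.random.Generator,
    cutoff: float = 200.0,
    cutoff_reference_size: int = 512,
    variance_target: float = 0.2,
) -> ImageEnsemble:
    """Synthetic pre-whitened training ensemble.

    Pink-noise images are passed through the whitening filter (cutoff
    200 cycles/image at the 512-pixel reference scale by default) and
    rescaled by a single global factor to pooled pixel variance
    ``variance_target`` (0.2 by default), reproducing the preparation of
    the natural-image training set.
    """
    ensemble = generate_pink_noise_ensemble(n_images, size, seed)
    spec = FilterSpec("whitening", cutoff, image_size=cutoff_reference_size)
    amplitude = build_filter(spec, size)
    whitened = apply_zero_phase_filter(ensemble, amplitude)
    return whitened.scaled_to_variance(variance_target)


def white_noise_patches(
    n: int,
    patch_size: int,
    variance: float,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Gaussian white-noise patches with the given per-pixel variance."""
    rng = np.random.default_rng(rng)
    return rng.normal(0.0, np.sqrt(variance), size=(n, patch_size, patch_size))


def sample_patches(
    ensemble: ImageEnsemble,
    n_patches: int,
    patch_size: int = 16,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw patches at uniformly random positions in uniformly random images."""
    rng = np.random.default_rng(rng)
    size = ensemble.size
    if patch_size > size:
        raise ValueError("patch_size exceeds image size")
    idx = rng.integers(0, ensemble.n_images, size=n_patches)
    top = rng.integers(0, size - patch_size + 1, size=n_patches)
    left = rng.integers(0, size - patch_size + 1, size=n_patches)
    out = np.empty((n_patches, patch_size, patch_size))
    for k in range(n_patches):
        out[k] = ensemble.images[
            idx[k], top[k] : top[k] + patch_size, left[k] : left[k] + patch_size
        ]
    return out


def encode_on_off(patch: np.ndarray) -> OnOffStimulus:
    """Split a signed patch into complementary non-negative ON/OFF vectors."""
    patch = np.asarray(patch, dtype=float)
    flat = patch.ravel(order="C")
    return OnOffStimulus(
        x_on=np.maximum(flat, 0.0),
        x_off=np.maximum(-flat, 0.0),
        patch_shape=patch.shape,
    )


def encode_batch(patches: np.ndarray) -> np.ndarray:
    """Encode a stack of patches into a (2N, batch) ON/OFF input matrix."""
    patches = np.asarray(patches, dtype=float)
    flat = patches.reshape(patches.shape[0], -1).T  # (N, batch)
    return np.concatenate([np.maximum(flat, 0.0), np.maximum(-flat, 0.0)], axis=0)


MAX_GRATING_RADIUS = 8.0  # half-width of the 16x16 patch, pixels


def generate_grating(spec: GratingSpec) -> np.ndarray:
    """Render a circular sinusoidal grating patch.

    Inside the aperture the value is
    ``contrast * cos(2*pi*f*x' + phase)`` where ``x'`` is the coordinate
    projected onto the grating's propagation axis; outside it is 0.  The
    aperture is centred on the patch centre.  A radius larger than the
    maximum (8 pixels for a 16-pixel patch) is clamped with a warning.
    """
    radius = spec.radius
    max_radius = spec.patch_size / 2.0
    if radius > max_radius:
        warnings.warn(
            f"grating radius {radius} exceeds the maximum {max_radius:.0f} px "
            "for this patch; clamping",
            stacklevel=2,
        )
        radius = max_radius
    if radius <= 0:
        raise ValueError("grating radius must be positive")
    P = spec.patch_size
    c = (P - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(P), np.arange(P), indexing="ij")
    x = cols - c
    y = rows - c
    theta = np.deg2rad(spec.orientation)
    proj = x * np.cos(theta) + y * np.sin(theta)
    carrier = spec.contrast * np.cos(
        2.0 * np.pi * spec.spatial_frequency * proj + np.deg2rad(spec.phase)
    )
    aperture = np.hypot(x, y) <= radius
    return np.where(aperture, carrier, 0.0)


def grating_grid(
    sigma_min: float,
    patch_size: int = 16,
    contrast: float = 1.0,
) -> list[GratingSpec]:
    """Enumerate the preferred-grating search grid for one cell.

    Radius runs from 1 pixel to ``min(2.5 * sigma_min, 8)`` in 1-pixel
    steps; spatial frequency, orientation, and phase run over the
    standard grids.
    """
    r_max = min(2.5 * sigma_min, MAX_GRATING_RADIUS)
    radii = np.arange(1.0, np.floor(r_max) + 1.0)
    if radii.size == 0:
        radii = np.array([1.0])
    return [
        GratingSpec(r, f, o, p, contrast, patch_size)
        for r in radii
        for f in SPATIAL_FREQUENCY_GRID
        for o in ORIENTATION_GRID
        for p in PHASE_GRID
    ]
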