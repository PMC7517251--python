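"""Synthetic binary stimulus generators.

Three sources feed the encoding pipeline, none requiring downloads:

* 2-D Ising lattice configurations at a controlled temperature, drawn by
  Swendsen-Wang cluster updates or Metropolis sweeps (periodic boundaries,
  ferromagnetic coupling J=1, k_B=1);
* spatially correlated binary images: Gaussian random fields smoothed at a
  chosen correlation length and binarized at each image's own median, a
  stand-in for median-binarized grayscale natural images;
* circular patches cut from either source, vectorized in a fixed raster
  order, yielding the binary stimulus vectors the encoder is trained on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._ising import run_metropolis, run_swendsen_wang
from .patterns import PatternDataset

__all__ = [
    "LatticeSampleSet",
    "BinaryImageSet",
    "PatchSpec",
    "onsager_critical_temperature",
    "onsager_magnetization",
    "sample_ising",
    "generate_binary_textures",
    "extract_patches",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class LatticeSampleSet:
    """Spin configurations of a 2-D Ising model at one temperature.

    ``configurations`` holds 0/1 cells under the mapping s = (sigma+1)/2;
    ``temperature`` is dimensionless (J = k_B = 1).
    """

    configurations: np.ndarray  # (n, L, L) uint8
    temperature: float
    sampler_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.configurations, dtype=np.uint8)
        if c.ndim != 3 or c.shape[1] != c.shape[2]:
            raise ValueError("configurations must have shape (n, L, L)")
        if c.max(initial=0) > 1:
            raise ValueError("lattice cells must be 0 or 1")
        self.configurations = c

    @property
    def side(self) -> int:
        return self.configurations.shape[1]

    @property
    def n_samples(self) -> int:
        return self.configurations.shape[0]

    def spins(self) -> np.ndarray:
        """Configurations in the ±1 spin convention."""
        return self.configurations.astype(np.int8) * 2 - 1

    def magnetization(self) -> np.ndarray:
        """Per-configuration mean spin (±1 convention)."""
        return self.spins().reshape(self.n_samples, -1).mean(axis=1)


@dataclass
class BinaryImageSet:
    """Binary images produced by median-thresholding a correlated field."""

    images: np.ndarray  # (n, H, W) uint8
    correlation_length: float
    threshold_rule: str = "median"

    def __post_init__(self) -> None:
        im = np.asarray(self.images, dtype=np.uint8)
        if im.ndim != 3:
            raise ValueError("images must have shape (n, H, W)")
        if im.max(initial=0) > 1:
            raise ValueError("image pixels must be 0 or 1")
        self.images = im


@dataclass(frozen=True)
class PatchSpec:
    """Circular patch geometry: an integer-offset disk around a center cell.

    The in-mask offsets are ordered row-major (top-to-bottom within rows,
    left-to-right within a row), a fixed public convention that defines the
    raster order of every extracted stimulus vector.
    """

    radius: float

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of (dy, dx) offsets with dy²+dx² ≤ radius²."""
        r = int(math.floor(self.radius))
        offs = [
            (dy, dx)
            for dy in range(-r, r + 1)
            for dx in range(-r, r + 1)
            if dy * dy + dx * dx <= self.radius * self.radius
        ]
        return np.array(offs, dtype=np.int64)

    @property
    def pixel_count(self) -> int:
        return len(self.offsets)

    @classmethod
    def from_pixel_count(cls, pixel_count: int) -> "PatchSpec":
        """Smallest-radius disk containing exactly ``pixel_count`` cells.

        The standard stimulus sizes 13, 21 and 37 pixels correspond to
        radii 2, 2.5 and 3.5.
        """
        # squared distances of integer offsets are integers or .25 multiples;
        # scan candidate radii on a fine grid
        for r in np.arange(1.0, 12.01, 0.5):
            spec = cls(radius=float(r))
            if spec.pixel_count == pixel_count:
                return spec
            if spec.pixel_count > pixel_count:
                break
        raise ValueError(f"no integer-offset disk has exactly {pixel_count} cells")


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def onsager_critical_temperature() -> float:
    """Exact critical temperature of the square-lattice Ising model.

    Returns Tc = 2/ln(1+sqrt(2)) ≈ 2.269, in units where J = k_B = 1,
    the Onsager solution of sinh(2/Tc) = 1.
    """
    return 2.0 / math.log(1.0 + math.sqrt(2.0))


def onsager_magnetization(T: float) -> float:
    """Spontaneous magnetization (1 - sinh(2/T)^-4)^(1/8), 0 above Tc."""
    if T >= onsager_critical_temperature():
        return 0.0
    return (1.0 - math.sinh(2.0 / T) ** -4) ** 0.125


def sample_ising(
    L: int,
    T: float,
    n_samples: int,
    burn_in: int = 1000,
    thin: int = 1,
    seed: int = 0,
    method: str = "swendsen-wang",
) -> LatticeSampleSet:
    """Draw Ising configurations on an L×L torus at temperature T.

    One Swendsen-Wang step is a full cluster decomposition and flip; one
    Metropolis sweep is L² random single-site proposals.  ``burn_in`` and
    ``thin`` are counted in these units.  Both methods target the same
    Boltzmann distribution exp(+sum_<ij> sigma_i sigma_j / T).
    """
    if L < 2:
        raise ValueError("lattice side L must be at least 2")
    if T <= 0:
        raise ValueError("temperature must be positive")
    if n_samples < 1 or burn_in < 1 or thin < 1:
        raise ValueError("n_samples, burn_in and thin must be positive")
    # numba's RNG takes uint32 seeds
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    if method == "swendsen-wang":
        flat = run_swendsen_wang(L, float(T), n_samples, burn_in, thin, kernel_seed)
    elif method == "metropolis":
        flat = run_metropolis(L, float(T), n_samples, burn_in, thin, kernel_seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    configs = ((flat + 1) // 2).astype(np.uint8).reshape(n_samples, L, L)
    return LatticeSampleSet(
        configurations=configs,
        temperature=float(T),
        sampler_meta={
            "algorithm": method,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
        },
    )


def generate_binary_textures(
    n_images: int,
    height: int,
    width: int,
    correlation_length: float,
    seed: int = 0,
) -> BinaryImageSet:
    """Spatially correlated binary images, median-binarized per image.

    White Gaussian noise is smoothed with an isotropic Gaussian kernel of
    standard deviation ``correlation_length`` (0 = iid bits), then each
    image is thresholded at its own median pixel value, so close to half
    of the pixels are set (exactly half for even pixel counts, up to ties).
    """
    if n_images < 1 or height < 1 or width < 1:
        raise ValueError("n_images, height and width must be positive")
    if correlation_length < 0:
        raise ValueError("correlation_length must be non-negative")
    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((n_images, height, width))
    if correlation_length > 0:
        fields = ndimage.gaussian_filter(
            fields, sigma=(0.0, correlation_length, correlation_length), mode="wrap"
        )
    medians = np.median(fields.reshape(n_images, -1), axis=1)
    images = (fields > medians[:, None, None]).astype(np.uint8)
    return BinaryImageSet(
        images=images,
        correlation_length=float(correlation_length),
        threshold_rule="median",
    )


def extract_patches(
    source: LatticeSampleSet | BinaryImageSet,
    spec: PatchSpec,
    n_patches: int,
    seed: int = 0,
) -> PatternDataset:
    """Cut circular binary patches at uniform random centers.

    Lattice sources wrap periodically (consistent with their boundary
    conditions); image sources restrict centers so the whole mask lies
    inside the frame.  Each patch is vectorized in the spec's raster order.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be positive")
    offsets = spec.offsets
    if isinstance(source, LatticeSampleSet):
        frames = source.configurations
        wrap = True
        meta = {
            "source": "ising",
            "temperature": source.temperature,
            **{f"sampler_{k}": v for k, v in source.sampler_meta.items()},
        }
    elif isinstance(source, BinaryImageSet):
        frames = source.images
        wrap = False
        meta = {
            "source": "textures",
            "correlation_length": source.correlation_length,
        }
    else:
        raise TypeError("source must be a LatticeSampleSet or BinaryImageSet")
    n_frames, H, W = frames.shape
    dy, dx = offsets[:, 0], offsets[:, 1]
    rng = np.random.default_rng(seed)
    frame_idx = rng.integers(0, n_frames, size=n_patches)
    if wrap:
        cy = rng.integers(0, H, size=n_patches)
        cx = rng.integers(0, W, size=n_patches)
        rows = (cy[:, None] + dy[None, :]) % H
        cols = (cx[:, None] + dx[None, :]) % W
    else:
        ylo, yhi = -dy.min(), H - dy.max()
        xlo, xhi = -dx.min(), W - dx.max()
        if yhi <= ylo or xhi <= xlo:
            raise ValueError("patch mask does not fit inside the image frame")
        cy = rng.integers(ylo, yhi, size=n_patches)
        cx = rng.integers(xlo, xhi, size=n_patches)
        rows = cy[:, None] + dy[None, :]
        cols = cx[:, None] + dx[None, :]
    vectors = frames[frame_idx[:, None], rows, cols]
    meta.update({"patch_radius": spec.radius, "n_patches": n_patches, "seed": seed})
    return PatternDataset(vectors=vectors, meta=meta)
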