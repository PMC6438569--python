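"""First-stage oriented-energy front end: x = phi(I).

A stimulus image is filtered by a quadrature pair of fine-scale Gabor
filters matched to the carrier (one channel per carrier orientation), the
even- and odd-phase responses are squared and summed into a local energy
map (the standard V1 complex-cell energy model), energies are divisively
normalized by the mean energy pooled over the image and all channels, and
each normalized map is downsampled onto a coarse grid by one of three
pooling rules (AVG / MAX / SUB).  The concatenated grid values form the
feature vector seen by the second-stage filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import ExperimentDesign, StimulusImage

GUARD_EPS = 1e-6  # relative guard constant in divisive normalization

POOLING_RULES = ("AVG", "MAX", "SUB")


@dataclass(frozen=True)
class ChannelParams:
    """One first-stage energy channel.

    The filter wavelength is matched to the carrier micropattern wavelength
    and the Gaussian envelope s.d. is wavelength/2 (circular).
    """

    orientation: float = 0.0
    wavelength: float = 32.0
    sigma: float | None = None  # defaults to wavelength / 2

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def envelope_sd(self) -> float:
        return self.sigma if self.sigma is not None else self.wavelength / 2.0


@dataclass(frozen=True)
class FrontendConfig:
    channels: tuple[ChannelParams, ...]
    grid: int = 16
    pooling: str = "AVG"

    def __post_init__(self) -> None:
        if self.pooling not in POOLING_RULES:
            raise ValueError(f"pooling must be one of {POOLING_RULES}")
        if self.grid < 1:
            raise ValueError("grid must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_features(self) -> int:
        return self.grid**2 * self.n_channels

    def to_dict(self) -> dict:
        return {
            "channels": [asdict(c) for c in self.channels],
            "grid": self.grid,
            "pooling": self.pooling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrontendConfig":
        return cls(
            channels=tuple(ChannelParams(**c) for c in d["channels"]),
            grid=int(d["grid"]),
            pooling=str(d["pooling"]),
        )

    @classmethod
    def for_design(cls, design: ExperimentDesign, grid: int | None = None,
                   pooling: str = "AVG") -> "FrontendConfig":
        """Channels matched to the design's carrier (one per carrier orientation,
        0 deg block first for serialization stability)."""
        wavelength = float(design.carrier.micropattern_size)
        channels = tuple(
            ChannelParams(orientation=o, wavelength=wavelength)
            for o in sorted(design.carrier.orientations)
        )
        return cls(channels=channels, grid=grid or design.default_grid, pooling=pooling)


def gabor_quadrature_kernel(channel: ChannelParams) -> np.ndarray:
    """Complex Gabor kernel; real part = even phase, imaginary part = odd phase.

    Zero-mean corrected so a constant image elicits exactly zero energy.
    """
    sd = channel.envelope_sd
    half = int(np.ceil(3 * sd))
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    th = np.deg2rad(channel.orientation)
    u = xx * np.cos(th) + yy * np.sin(th)
    v = -xx * np.sin(th) + yy * np.cos(th)
    envelope = np.exp(-(u**2 + v**2) / (2 * sd**2))
    kernel = envelope * np.exp(2j * np.pi * u / channel.wavelength)
    # remove the (small) DC component of the even-phase lobe
    kernel = kernel - envelope * (kernel.real.sum() / envelope.sum())
    return kernel


def gabor_energy(image: np.ndarray, channel: ChannelParams) -> np.ndarray:
    """Local oriented energy: squared quadrature-pair responses, summed.

    Convolution uses symmetric (reflective) boundary padding to avoid rim
    artifacts; the output has the same shape as the input.
    """
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    kernel = gabor_quadrature_kernel(channel)
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="symmetric")
    response = fftconvolve(padded, kernel, mode="valid")
    return np.abs(response) ** 2


def normalize_energy(energy_maps, eps: float = GUARD_EPS):
    """Divisive normalization by the mean energy pooled over image and channels.

    Accepts a single map or a sequence of per-channel maps; the pooled mean is
    taken over all of them, so the output is invariant to rescaling the input
    image contrast (up to the guard constant).  An all-zero input maps to zero.
    """
    single = isinstance(energy_maps, np.ndarray)
    maps = [energy_maps] if single else list(energy_maps)
    pooled = float(np.mean([m.mean() for m in maps]))
    denom = pooled + eps * (pooled if pooled > 0 else 1.0)
    out = [m / denom if denom > 0 else np.zeros_like(m) for m in maps]
    return out[0] if single else out


def downsample(array: np.ndarray, grid: int, rule: str) -> np.ndarray:
    """Pool an energy map onto a grid x grid lattice; returns a row-major vector.

    AVG = block mean, MAX = block max, SUB = the block's center element
    (index block_size // 2 along each axis for even block sizes).

    A map whose side is not a multiple of ``grid`` is first padded
    symmetrically (reflective) to the next multiple, split as evenly as
    possible between the two sides (extra pixel at the trailing edge).
    """
    if rule not in POOLING_RULES:
        raise ValueError(f"rule must be one of {POOLING_RULES}")
    if array.shape[0] != array.shape[1]:
        raise ValueError("expected a square map")
    n = array.shape[0]
    if n % grid:
        target = int(np.ceil(n / grid)) * grid
        before = (target - n) // 2
        after = target - n - before
        array = np.pad(array, ((before, after), (before, after)), mode="symmetric")
        n = target
    b = n // grid
    blocks = array.reshape(grid, b, grid, b)
    if rule == "AVG":
        out = blocks.mean(axis=(1, 3))
    elif rule == "MAX":
        out = blocks.max(axis=(1, 3))
    else:  # SUB
        out = blocks[:, b // 2, :, b // 2]
    return out.reshape(-1)


def featurize_image(pixels: np.ndarray, config: FrontendConfig) -> np.ndarray:
    """Full front end for one image: energy -> normalize -> downsample -> concat."""
    energies = [gabor_energy(pixels, ch) for ch in config.channels]
    normalized = normalize_energy(energies)
    return np.concatenate([downsample(m, config.grid, config.pooling) for m in normalized])


def featurize(stimulus: StimulusImage, config: FrontendConfig) -> np.ndarray:
    return featurize_image(stimulus.pixels, config)


def feature_matrix(stimuli, config: FrontendConfig) -> np.ndarray:
    """Stack feature vectors for an iterable of stimuli into an (n, d) matrix."""
    return np.array([featurize(s, config) for s in stimuli])


def save_features(path, X: np.ndarray, config: FrontendConfig) -> None:
    """Portable feature cache: JSON header line + rows of text floats."""
    header = json.dumps(config.to_dict())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, X, fmt="%.17g")


def load_features(path) -> tuple[np.ndarray, FrontendConfig]:
    with open(path) as fh:
        config = FrontendConfig.from_dict(json.loads(fh.readline()))
        X = np.loadtxt(fh, ndmin=2)
    if X.shape[1] != config.n_features:
        raise ValueError("feature file does not match its recorded config")
    return X, config
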