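"""Contrast-modulated micropattern boundary stimuli.

A stimulus is the product of three images: a dense *carrier* texture built
from randomly placed odd-phase Gabor micropatterns, a half-disc contrast
*envelope* that is high on one side of an oblique boundary and low on the
other, and a circular *window* that fades the whole pattern into the
mean-luminance background.  All images are held as zero-mean luminance
*contrast* arrays (background = 0); 8-bit quantization happens only when
writing PNG files.

Coordinate conventions: row-major arrays, origin top-left, x rightward,
y downward; boundary orientation is measured in degrees clockwise from
vertical (as seen by the viewer), so +45 is a right-oblique boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve


@dataclass(frozen=True)
class CarrierParams:
    """Parameters of the micropattern carrier texture.

    ``rms_contrast`` is the global root-mean-square contrast the carrier is
    rescaled to after generation.  ``uniformity_tolerance`` is the maximum
    allowed fractional deviation of block-wise rms contrast (on an
    ``uniformity_grid`` x ``uniformity_grid`` partition) from the global rms;
    carriers violating it are rejected and resampled.
    """

    image_size: int = 256
    micropattern_count: int = 2048
    micropattern_size: int = 32
    aspect_ratio: float = 1.0
    orientations: tuple[float, ...] = (0.0,)
    rms_contrast: float = 0.14
    oversize_margin: int | None = None  # defaults to micropattern_size
    uniformity_tolerance: float = 0.25
    uniformity_grid: int = 4
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.rms_contrast < 1.0:
            raise ValueError("rms_contrast must lie in (0, 1)")
        if self.micropattern_count < 1:
            raise ValueError("micropattern_count must be >= 1")
        if self.micropattern_size > self.image_size:
            raise ValueError("micropattern_size must not exceed image_size")

    @property
    def margin(self) -> int:
        return self.oversize_margin if self.oversize_margin is not None else self.micropattern_size


@dataclass(frozen=True)
class EnvelopeParams:
    """Half-disc contrast modulation envelope.

    ``orientation`` is the boundary orientation in degrees clockwise from
    vertical; ``phase`` (0 or 180) selects which side carries the high
    contrast; ``modulation_depth`` is the Michelson modulation m of the
    contrast across the boundary.  The boundary transition and the outer rim
    of the circular window are half-cosine tapers over ``taper_fraction`` of
    the stimulus width.
    """

    orientation: float = 45.0
    phase: int = 0
    modulation_depth: float = 0.32
    taper_fraction: float = 0.2
    window_radius: float | None = None  # defaults to image_size / 2
    image_size: int = 256

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not 0.0 < self.taper_fraction <= 0.5:
            raise ValueError("taper_fraction must lie in (0, 0.5]")
        if self.phase not in (0, 180):
            raise ValueError("phase must be 0 or 180 degrees")

    @property
    def radius(self) -> float:
        return self.window_radius if self.window_radius is not None else self.image_size / 2.0


@dataclass
class StimulusImage:
    """A generated stimulus: contrast pixels plus generation metadata."""

    pixels: np.ndarray
    stimulus_id: str
    category: str  # 'L' or 'R'
    level: float  # modulation depth m
    phase: int  # 0 or 180
    orientation_deg: float
    seed: int


def micropattern(size: int, orientation: float = 0.0, aspect_ratio: float = 1.0) -> np.ndarray:
    """One odd-phase (sine) Gabor micropattern.

    The Gaussian envelope s.d. is size/4 so the nominal size spans +/- 2 s.d.,
    and the carrier wavelength equals the nominal size (one full cycle across
    the pattern).  ``aspect_ratio`` elongates the envelope along the pattern's
    own orientation axis.
    """
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    th = np.deg2rad(orientation)
    # coordinates along (u) and across (v) the micropattern's stripes
    u = xx * np.cos(th) + yy * np.sin(th)  # across-stripe axis for vertical pattern
    v = -xx * np.sin(th) + yy * np.cos(th)
    sd = size / 4.0
    envelope = np.exp(-(u**2 / (2 * sd**2) + v**2 / (2 * (aspect_ratio * sd) ** 2)))
    grating = np.sin(2 * np.pi * u / size)  # odd phase: zero at the center
    return envelope * grating


def make_carrier(params: CarrierParams, seed: int) -> np.ndarray:
    """Generate a carrier texture of ``image_size**2`` pixels.

    Micropatterns are placed at uniformly random integer positions in an
    oversize image (margin = micropattern size on each side), summed
    additively, and the result cropped centrally.  For multi-orientation
    carriers the patterns are drawn equally from each orientation.  Carriers
    failing the block-rms uniformity criterion are rejected and resampled;
    the accepted carrier is rescaled so its global rms contrast equals
    ``params.rms_contrast`` exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_ori = len(params.orientations)
    counts = [params.micropattern_count // n_ori] * n_ori
    counts[0] += params.micropattern_count - sum(counts)
    patches = [
        micropattern(params.micropattern_size, o, params.aspect_ratio)
        for o in params.orientations
    ]
    big = params.image_size + 2 * params.margin
    for _ in range(params.max_attempts):
        image = np.zeros((big, big))
        for patch, count in zip(patches, counts):
            impulses = np.zeros((big, big))
            rows = rng.integers(0, big, size=count)
            cols = rng.integers(0, big, size=count)
            np.add.at(impulses, (rows, cols), 1.0)
            image += fftconvolve(impulses, patch, mode="same")
        lo = params.margin
        cropped = image[lo : lo + params.image_size, lo : lo + params.image_size]
        cropped = cropped - cropped.mean()
        rms = cropped.std()
        if rms == 0.0:
            continue
        carrier = cropped * (params.rms_contrast / rms)
        if _is_uniform(carrier, params):
            return carrier
    raise RuntimeError(
        f"no carrier passed the rms-uniformity criterion in {params.max_attempts} "
        "attempts; the uniformity tolerance is probably too strict for this density"
    )


def _is_uniform(carrier: np.ndarray, params: CarrierParams) -> bool:
    g = params.uniformity_grid
    n = params.image_size
    block = n // g
    trimmed = carrier[: g * block, : g * block]
    blocks = trimmed.reshape(g, block, g, block).swapaxes(1, 2).reshape(g * g, -1)
    block_rms = np.sqrt((blocks**2).mean(axis=1))
    global_rms = np.sqrt((trimmed**2).mean())
    return bool(np.all(np.abs(block_rms - global_rms) <= params.uniformity_tolerance * global_rms))


def _half_cosine_step(s: np.ndarray, taper: float) -> np.ndarray:
    """Ramp from -1 to +1 over ``taper`` pixels, half-cosine shaped, centered at 0."""
    out = np.sign(s).astype(float)
    inside = np.abs(s) <= taper / 2.0
    out[inside] = np.sin(np.pi * s[inside] / taper)
    return out


def make_envelope(params: EnvelopeParams) -> tuple[np.ndarray, np.ndarray]:
    """Return the boundary envelope E in [-1, 1] and circular window w in [0, 1].

    E transitions from -1 to +1 by a half-cosine over ``taper_fraction`` of the
    image width, along the normal of a boundary line through the image center.
    At phase 0 the high side is the side toward the bottom of the image (the
    +x side for an exactly vertical boundary); phase 180 negates E.  w is 1
    inside the circular window and decays to 0 at the rim by a half-cosine
    over the same taper width.
    """
    n = params.image_size
    c = (n - 1) / 2.0
    ax = np.arange(n, dtype=float)
    xx, yy = np.meshgrid(ax - c, ax - c)
    th = np.deg2rad(params.orientation)
    s = xx * np.cos(th) + yy * np.sin(th)  # signed distance from boundary line
    taper = params.taper_fraction * n
    side = np.sign(np.sin(th)) if params.orientation != 0.0 else 1.0
    if side == 0.0:
        side = 1.0
    env = side * _half_cosine_step(s, taper)
    if params.phase == 180:
        env = -env
    r = np.hypot(xx, yy)
    radius = params.radius
    w = np.ones_like(r)
    rim = r > radius - taper
    w[rim] = 0.5 * (1.0 + np.cos(np.pi * (r[rim] - (radius - taper)) / taper))
    w[r > radius] = 0.0
    return env, w


def make_stimulus(
    carrier: np.ndarray, envelope: np.ndarray, window: np.ndarray, m: float
) -> np.ndarray:
    """Apply contrast modulation: pixels = w * (1 + m*E) * carrier.

    The local contrast scale is c0*(1 + m*E), so the two sides carry contrast
    c0*(1 +/- m) and m is the Michelson modulation of contrast.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation depth m must lie in [0, 1]")
    if carrier.shape != envelope.shape or carrier.shape != window.shape:
        raise ValueError("carrier, envelope and window must share dimensions")
    return window * (1.0 + m * envelope) * carrier


@dataclass(frozen=True)
class ExperimentDesign:
    """A full stimulus-set design: carrier, modulation levels and boundary geometry.

    ``boundary_orientation`` is the magnitude of the boundary tilt; category R
    uses +orientation (clockwise) and L uses -orientation.
    """

    name: str
    carrier: CarrierParams
    levels: tuple[float, ...]
    boundary_orientation: float
    taper_fraction: float = 0.2
    default_grid: int = 16

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _log_levels(lo: float, hi: float, n: int = 9) -> tuple[float, ...]:
    return tuple(np.geomspace(lo, hi, n))


_DESIGNS = {}


def _register_designs() -> None:
    base = CarrierParams()
    _DESIGNS["exp1_var"] = ExperimentDesign(
        name="exp1_var",
        carrier=base,
        levels=(0.0,) + _log_levels(0.08, 0.32),
        boundary_orientation=45.0,
        default_grid=16,
    )
    _DESIGNS["exp1_fix"] = ExperimentDesign(
        name="exp1_fix",
        carrier=base,
        levels=(0.16,),
        boundary_orientation=45.0,
        default_grid=16,
    )
    _DESIGNS["exp1_hfc"] = ExperimentDesign(
        name="exp1_hfc",
        carrier=replace(base, micropattern_count=8192, micropattern_size=8),
        levels=(0.0,) + _log_levels(0.08, 0.32),
        boundary_orientation=45.0,
        default_grid=16,
    )
    _DESIGNS["exp2_var"] = ExperimentDesign(
        name="exp2_var",
        carrier=base,
        levels=(0.0,) + _log_levels(0.16, 0.64),
        boundary_orientation=7.0,
        default_grid=22,
    )
    _DESIGNS["exp2_fix"] = ExperimentDesign(
        name="exp2_fix",
        carrier=base,
        levels=(0.32,),
        boundary_orientation=7.0,
        default_grid=22,
    )
    _DESIGNS["exp3"] = ExperimentDesign(
        name="exp3",
        carrier=replace(
            base, micropattern_count=512, aspect_ratio=2.0, orientations=(0.0, 90.0)
        ),
        levels=(0.0,) + _log_levels(0.08, 0.32),
        boundary_orientation=45.0,
        default_grid=12,
    )


_register_designs()


def get_design(name: str, jnd_deg: float | None = None) -> ExperimentDesign:
    """Look up one of the canonical designs.

    ``jnd_deg`` overrides the boundary perturbation of the fine-discrimination
    designs (each observer's just-noticeable difference, 6-7 deg in practice).
    """
    try:
        design = _DESIGNS[name]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(_DESIGNS)}") from None
    if jnd_deg is not None and name.startswith("exp2"):
        design = replace(design, boundary_orientation=jnd_deg)
    return design


def scaled_design(name: str, image_size: int, grid: int) -> ExperimentDesign:
    """A size-reduced variant of a canonical design (same modulation levels).

    Micropattern size and count shrink with the image so the pattern density
    per area is preserved; intended for quick simulations and unit tests.
    """
    design = get_design(name)
    factor = design.carrier.image_size / image_size
    carrier = replace(
        design.carrier,
        image_size=image_size,
        micropattern_size=max(4, round(design.carrier.micropattern_size / factor)),
        micropattern_count=max(8, round(design.carrier.micropattern_count / factor**2)),
        # fewer speckle cells per block at small sizes: coarser uniformity partition
        uniformity_grid=2,
    )
    return replace(design, name=f"{name}_s{image_size}", carrier=carrier, default_grid=grid)


def trial_plan(design: ExperimentDesign, n_trials: int, seed: int):
    """The deterministic per-trial schedule (level, category, phase, seed).

    Levels are balanced exactly (``n_trials`` must be divisible by the number
    of levels); category and phase are balanced within each level and then
    shuffled.  The per-trial carrier seed is spawned from ``seed`` and the
    trial index, so any single stimulus is reproducible in isolation.
    """
    k = design.n_levels
    if n_trials % k:
        raise ValueError(f"n_trials must be divisible by the number of levels ({k})")
    per = n_trials // k
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xD5,)))
    rows = []
    for level in design.levels:
        cats = np.repeat(["L", "R"], [per - per // 2, per // 2])
        phases = np.tile([0, 180], per)[:per]
        rng.shuffle(cats)
        rng.shuffle(phases)
        for c, p in zip(cats, phases):
            rows.append((float(level), str(c), int(p)))
    order = rng.permutation(len(rows))
    plan = []
    for idx, j in enumerate(order):
        level, cat, phase = rows[j]
        trial_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0])
        plan.append((idx, level, cat, phase, trial_seed))
    return plan


def iter_stimulus_set(design: ExperimentDesign, n_trials: int, seed: int):
    """Yield ``StimulusImage`` objects for a design, one per trial.

    Every trial draws a fresh carrier (an observer never sees the same
    carrier twice).  Streaming generator: large sets need not be held in
    memory at once.
    """
    env_cache: dict[tuple[float, int, float], tuple[np.ndarray, np.ndarray]] = {}
    for idx, level, cat, phase, trial_seed in trial_plan(design, n_trials, seed):
        ori = design.boundary_orientation if cat == "R" else -design.boundary_orientation
        key = (ori, phase, level)
        if key not in env_cache:
            ep = EnvelopeParams(
                orientation=ori,
                phase=phase,
                modulation_depth=level,
                taper_fraction=design.taper_fraction,
                image_size=design.carrier.image_size,
            )
            env_cache[key] = make_envelope(ep)
        env, window = env_cache[key]
        carrier = make_carrier(design.carrier, trial_seed)
        pixels = make_stimulus(carrier, env, window, level)
        yield StimulusImage(
            pixels=pixels,
            stimulus_id=f"{design.name}-{seed}-{idx:06d}",
            category=cat,
            level=level,
            phase=phase,
            orientation_deg=ori,
            seed=trial_seed,
        )


def make_stimulus_set(design: ExperimentDesign, n_trials: int, seed: int) -> list[StimulusImage]:
    """Materialize a full stimulus set as a list (see :func:`iter_stimulus_set`)."""
    return list(iter_stimulus_set(design, n_trials, seed))


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Map contrast values to 8-bit grayscale with 128 = zero contrast."""
    return np.clip(np.round(pixels * 127.0 + 128.0), 0, 255).astype(np.uint8)
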