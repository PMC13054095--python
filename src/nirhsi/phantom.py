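"""Synthetic hyperspectral tissue-microarray phantoms.

Generates labeled cohorts of NIR hyperspectral cubes that emulate a
78-core pancreatic tissue microarray: each core is an elliptical tissue
region against a dimmer background, with a smooth NIR baseline spectrum
(broad overtone-like Gaussian bumps for water/lipid/protein bands), smooth
spatial texture blobs, a multiplicative illumination gradient and additive
Gaussian noise. Cancer cores carry an additive spectral signature of
amplitude ``effect_size * noise_sd`` at designated signature bands, inside
the elliptical lesion region only — so class separation is expressed in
noise-SD units and class-conditional distributions coincide exactly when
``effect_size = 0``.

Outlying samples (preparation artifacts, measurement faults) are planted
by a global gain factor plus band-localized additive spikes; their ids are
returned as ground truth so detector recovery can be scored.

Randomness: a single cohort seed spawns one independent stream per sample
(``SeedSequence(seed).spawn``), so cohorts are reproducible bit-for-bit
and extendable without rewriting earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .cube_io import HyperCube
from .errors import ConfigError

__all__ = ["PhantomConfig", "generate_cohort", "plant_outliers", "lesion_mask"]


@dataclass
class PhantomConfig:
    """Generator parameters; defaults emulate the 78-core study cohort.

    ``height/width/bands`` default to a desk-scale 64 x 64 x 16 core image
    (the full-resolution acquisition is 600 x 450 x 750); ``effect_size``
    is the separation of class mean spectra at signature bands in units of
    ``noise_sd``.
    """

    n_samples: int = 78
    cancer_fraction: float = 0.5
    height: int = 64
    width: int = 64
    bands: int = 16
    effect_size: float = 6.0
    noise_sd: float = 0.05
    illumination_gradient: float = 0.2
    n_outliers: int = 0
    outlier_severity: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not (0.0 < self.cancer_fraction < 1.0):
            raise ConfigError("cancer_fraction must lie in (0, 1)")
        if self.bands < 3:
            raise ConfigError("bands must be >= 3")
        if min(self.height, self.width) < 8:
            raise ConfigError("height and width must be >= 8")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ConfigError("effect_size must be finite and >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.illumination_gradient < 0:
            raise ConfigError("illumination_gradient must be >= 0")
        if self.n_outliers < 0 or self.n_outliers > self.n_samples:
            raise ConfigError("need 0 <= n_outliers <= n_samples")
        if self.outlier_severity < 0:
            raise ConfigError("outlier_severity must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def signature_bands(bands: int) -> np.ndarray:
    """Indices of the class-signature bands (fixed at ~30% and ~65% of the axis)."""
    return np.unique(np.array([int(0.3 * bands), int(0.65 * bands)]))


def _signature_profile(bands: int) -> np.ndarray:
    """Smooth band profile peaking at exactly 1 at the signature bands."""
    b = np.arange(bands)
    width = max(bands / 14.0, 1.0)
    prof = np.zeros(bands)
    for c in signature_bands(bands):
        prof = np.maximum(prof, np.exp(-0.5 * ((b - c) / width) ** 2))
    return prof


def _baseline_spectrum(bands: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of 2-3 broad Gaussian bumps over the band axis, jittered per sample."""
    b = np.arange(bands)
    centers = np.array([0.2, 0.5, 0.85]) * bands
    widths = np.array([0.18, 0.25, 0.15]) * bands
    amps = np.array([0.6, 1.0, 0.5]) * (1.0 + 0.02 * rng.standard_normal(3))
    spec = np.zeros(bands)
    for c, w, a in zip(centers, widths, amps):
        spec += a * np.exp(-0.5 * ((b - c) / w) ** 2)
    return 0.3 + spec


def lesion_mask(
    height: int, width: int, center: tuple[float, float], axes: tuple[float, float], angle: float
) -> np.ndarray:
    """Boolean mask of a rotated ellipse (the tissue-core / lesion region)."""
    r, c = np.ogrid[:height, :width]
    dr = r - center[0]
    dc = c - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _make_sample(
    idx: int, label: int, cfg: PhantomConfig, rng: np.random.Generator
) -> HyperCube:
    H, W, B = cfg.height, cfg.width, cfg.bands
    spec = _baseline_spectrum(B, rng)

    # elliptical tissue core, randomized geometry
    center = (
        H / 2 + rng.uniform(-0.06, 0.06) * H,
        W / 2 + rng.uniform(-0.06, 0.06) * W,
    )
    axes = (rng.uniform(0.28, 0.4) * H, rng.uniform(0.28, 0.4) * W)
    angle = rng.uniform(0, np.pi)
    core = lesion_mask(H, W, center, axes, angle)

    # smooth random texture blobs inside the core
    blobs = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=min(H, W) / 8)
    blobs = blobs / (blobs.std() + 1e-12)
    texture = np.where(core, 1.0 + 0.15 * blobs, 0.25)

    # multiplicative illumination plane, zero-mean tilt of max amplitude g
    g = cfg.illumination_gradient
    rr = np.linspace(-0.5, 0.5, H)[:, None]
    cc = np.linspace(-0.5, 0.5, W)[None, :]
    tilt = rng.uniform(-1, 1, size=2)
    illum = 1.0 + g * (tilt[0] * rr + tilt[1] * cc) * 2

    cube = texture[:, :, None] * spec[None, None, :] * illum[:, :, None]

    # class signature: additive, inside the lesion ellipse, at signature bands
    if label == 1 and cfg.effect_size > 0:
        delta = cfg.effect_size * cfg.noise_sd * _signature_profile(B)
        cube = cube + core[:, :, None] * delta[None, None, :]

    cube = cube + cfg.noise_sd * rng.standard_normal((H, W, B))
    cube -= min(0.0, float(cube.min()))  # keep counts non-negative

    wl = np.linspace(1000.0, 1750.0, B)
    meta = {
        "lesion_center": center,
        "lesion_axes": axes,
        "lesion_angle": angle,
        "is_outlier": False,
    }
    return HyperCube(f"S{idx:03d}", cube, wl, label=label, meta=meta)


def generate_cohort(config: PhantomConfig) -> tuple[list[HyperCube], np.ndarray]:
    """Generate a labeled cohort; outliers planted per ``config.n_outliers``.

    Returns the cubes and an int label vector. Planted outlier ids are
    recorded in each corrupted cube's ``meta['is_outlier']``.
    """
    cfg = config
    n = cfg.n_samples
    ss = np.random.SeedSequence(cfg.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    n_cancer = int(round(n * cfg.cancer_fraction))
    labels = np.zeros(n, dtype=int)
    labels[label_rng.permutation(n)[:n_cancer]] = 1

    sample_seeds = np.random.SeedSequence(cfg.seed).spawn(n + 2)
    cubes = [
        _make_sample(i, int(labels[i]), cfg, np.random.default_rng(sample_seeds[i + 1]))
        for i in range(n)
    ]
    if cfg.n_outliers > 0:
        outlier_seed = int(sample_seeds[n + 1].generate_state(1)[0] % (2**31))
        cubes, _ = plant_outliers(
            cubes, cfg.n_outliers, cfg.outlier_severity, seed=outlier_seed
        )
    return cubes, labels


def plant_outliers(
    cohort: list[HyperCube], n_outliers: int, severity: float, seed: int
) -> tuple[list[HyperCube], list[str]]:
    """Corrupt ``n_outliers`` randomly chosen samples; return (cohort, ids).

    Corruption = global gain ``x (1 + severity)`` plus additive spikes of
    amplitude ``severity * SD`` at three random bands — emulating tissue
    preparation artifacts and measurement faults. Non-chosen samples are
    returned untouched (same objects).
    """
    if severity < 0:
        raise ConfigError("severity must be >= 0")
    if n_outliers > len(cohort):
        raise ConfigError("n_outliers exceeds cohort size")
    if n_outliers == 0:
        return cohort, []
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(cohort), size=n_outliers, replace=False).tolist())
    out = list(cohort)
    ids = []
    for i in chosen:
        cube = cohort[i].copy()
        cube.data = cube.data * (1.0 + severity)
        # spike amplitude in units of the corrupted cube's own SD, so the
        # planted severity survives per-cube min-max renormalization
        sd = float(cube.data.std())
        spike_bands = rng.choice(cube.n_bands, size=min(3, cube.n_bands), replace=False)
        for b in spike_bands:
            cube.data[:, :, b] += severity * sd
        cube.meta["is_outlier"] = True
        out[i] = cube
        ids.append(cube.sample_id)
    return out, ids
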