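"""Seeded 3D texture phantoms, toy atlases, cohorts and region timecourses.

The phantoms stand in for registered anatomical brain volumes.  The
between-class signal is placed deliberately in *texture scale*, not mean
intensity: class 1 either gets a wider smoothing kernel (``smoothed_noise``)
or a different spatial frequency of a sinusoidal folding lattice
(``fold_pattern``).  Because LBP codes are invariant to any strictly
increasing intensity transform, a mean shift would be invisible to the
texture features; a smoothing-scale difference changes the code
distribution, which is exactly the kind of morphological alteration the
descriptor is meant to detect.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import LabelVolume, Volume


@dataclass
class PhantomSpec:
    """Generation parameters for one synthetic cohort condition.

    class_effect >= 0 controls the between-class texture difference
    (smoothing-width offset in voxels, or relative fold-frequency change);
    0 makes the two class-conditional distributions identical.
    """

    shape: tuple = (32, 32, 32)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    n_regions: int = 1
    class_effect: float = 2.0
    texture_kind: str = "smoothed_noise"
    noise_sd: float = 0.05
    seed: int = 0
    base_sigma: float = 1.0  # class-0 smoothing width, voxels
    base_freq: float = 0.08  # class-0 fold frequency, cycles/voxel
    probability_mode: bool = False  # squash into [0,1] to emulate tissue maps

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture_kind not in ("smoothed_noise", "fold_pattern"):
            raise ValueError(f"unknown texture_kind {self.texture_kind!r}")
        if min(self.shape) < 12:
            raise ValueError("phantom too small for radius-3 neighborhoods")


def _ellipsoid_mask(shape) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.42 * np.asarray(shape)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def _slab_atlas(mask: np.ndarray, n_regions: int) -> np.ndarray:
    """Contiguous equal-extent slabs along the first axis, inside the mask."""
    labels = np.zeros(mask.shape, dtype=np.int64)
    xs = np.nonzero(mask.any(axis=(1, 2)))[0]
    x_min, x_max = xs[0], xs[-1]
    span = x_max - x_min + 1
    xcoord = np.arange(mask.shape[0])[:, None, None]
    region = 1 + np.minimum((xcoord - x_min) * n_regions // span, n_regions - 1)
    labels[mask] = np.broadcast_to(region, mask.shape)[mask]
    return labels


def generate_atlas(spec: PhantomSpec) -> LabelVolume:
    """The cohort's shared mask/parcellation (deterministic, no randomness)."""
    mask = _ellipsoid_mask(spec.shape)
    return LabelVolume(_slab_atlas(mask, spec.n_regions), spec.spacing_mm)


def generate_phantom(spec: PhantomSpec, class_id: int):
    """One subject's volume plus the shared atlas; deterministic in (seed, class_id)."""
    if class_id not in (0, 1):
        raise ValueError("class_id must be 0 or 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, class_id]))
    data = _texture(spec, class_id, rng)
    return Volume(data, spec.spacing_mm), generate_atlas(spec)


def _texture(spec: PhantomSpec, class_id: int, rng) -> np.ndarray:
    if spec.texture_kind == "smoothed_noise":
        sigma = spec.base_sigma + spec.class_effect * class_id
        data = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma)
        data /= max(data.std(), 1e-12)  # texture scale carries the signal, not amplitude
    else:  # fold_pattern: sinusoidal "gyrification" lattice
        freq = spec.base_freq * (1.0 + spec.class_effect * class_id)
        grids = np.meshgrid(*[np.arange(n) for n in spec.shape], indexing="ij")
        phases = rng.uniform(0, 2 * np.pi, size=3)
        data = np.prod(
            [np.sin(2 * np.pi * freq * g + ph) for g, ph in zip(grids, phases)], axis=0
        )
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(spec.shape)
    if spec.probability_mode:
        data = 1.0 / (1.0 + np.exp(-2.0 * data))
    return data


def generate_cohort(spec: PhantomSpec, n_per_class: int):
    """A balanced two-class cohort with a shared atlas.

    Subjects get independent sub-seeds derived deterministically from
    ``spec.seed``.  Returns (volumes, classes, atlas, labels_df); subjects
    alternate classes so ids are stable under cohort-size changes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    atlas = generate_atlas(spec)
    volumes, classes, sids = [], [], []
    for i in range(n_per_class):
        for cls in (0, 1):
            sub_seed = int(
                np.random.SeedSequence([spec.seed, cls, i]).generate_state(1)[0] % (2**31)
            )
            vol, _ = generate_phantom(replace(spec, seed=sub_seed), cls)
            volumes.append(vol)
            classes.append(cls)
            sids.append(f"sub-{len(sids):03d}")
    labels = pd.DataFrame({"subject_id": sids, "class": classes})
    return volumes, np.array(classes), atlas, labels


def generate_timecourses(
    n_regions: int,
    n_timepoints: int,
    block_correlation: float = 0.0,
    seed: int = 0,
    block_size: int | None = None,
) -> np.ndarray:
    """Gaussian region timecourses with block-structured target correlation.

    Regions are split into contiguous blocks of ``block_size`` (default: one
    block spanning all regions); within-block pairs target
    ``block_correlation``, across-block pairs 0.  Returns a regions x
    timepoints matrix, deterministic in ``seed``.
    """
    if n_regions < 2 or n_timepoints < 3:
        raise ValueError("need n_regions >= 2 and n_timepoints >= 3")
    if not -1 < block_correlation < 1:
        raise ValueError(f"|block_correlation| must be < 1, got {block_correlation}")
    if block_size is None:
        block_size = n_regions
    target = np.eye(n_regions)
    for start in range(0, n_regions, block_size):
        stop = min(start + block_size, n_regions)
        target[start:stop, start:stop] = block_correlation
    np.fill_diagonal(target, 1.0)
    L = np.linalg.cholesky(target)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal((n_regions, n_timepoints))
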