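"""Simulation-as-augmentation batching and MR-style corruptions.

A training batch holds N patches of the *same* subject at the *same*
location, each simulated with independently sampled sequence parameters,
and exactly one shared label patch — the structure the stratification
loss requires.  Because the static equations are voxelwise, simulation is
restricted to the patch (restriction commutes with the signal model).

Spatial augmentations (one affine + free-form deformation per batch) are
shared by all members and the label, preserving label identity across
members; intensity corruptions (bias field, noise, blur) are sampled
independently per member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .labels import SoftLabelMap
from .phantom import MPMVolume
from .simulate import ParamRanges, physics_vector, sample_params, simulate

__all__ = [
    "AugmentationConfig",
    "TrainingBatch",
    "build_batch",
    "apply_bias_field",
    "add_noise",
    "apply_spatial_augs",
]


@dataclass
class AugmentationConfig:
    """Corruption magnitudes; all amplitudes >= 0.  Gamma/contrast
    augmentation is deliberately absent — contrast must stay attributable
    to the sequence parameters."""

    bias_field_order: int = 3
    bias_field_amplitude: float = 0.3
    noise_sd_range: tuple[float, float] = (0.02, 0.1)
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_vox: float = 2.0
    ffd_grid: int = 4
    ffd_max_displacement_vox: float = 4.0
    blur_sd_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.bias_field_amplitude < 0 or self.ffd_max_displacement_vox < 0:
            raise ValueError("augmentation amplitudes must be non-negative")
        if self.noise_sd_range[0] < 0 or self.blur_sd_range[0] < 0:
            raise ValueError("augmentation amplitudes must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(
            bias_field_amplitude=0.0,
            noise_sd_range=(0.0, 0.0),
            rotation_deg=0.0,
            scale_range=(1.0, 1.0),
            translation_vox=0.0,
            ffd_max_displacement_vox=0.0,
            blur_sd_range=(0.0, 0.0),
        )


@dataclass
class TrainingBatch:
    """N same-subject, same-location, different-contrast patches with one
    shared label patch."""

    images: np.ndarray  # (N, P, P, P)
    physics: np.ndarray  # (N, len) encoded conditioning vectors
    params: list
    labels: SoftLabelMap  # the single shared (4, P, P, P) label patch
    subject_id: str
    patch_origin: tuple[int, int, int]

    @property
    def n(self) -> int:
        return self.images.shape[0]


def build_batch(
    mpm: MPMVolume,
    labels: SoftLabelMap,
    ranges: ParamRanges,
    n: int,
    patch_size: int,
    rng: np.random.Generator,
    params_list=None,
    magnitude: bool = False,
) -> TrainingBatch:
    """Sample one patch origin and N parameter draws; simulate N patches.

    ``params_list`` overrides random parameter sampling (pre-generated
    contrast mode): entries are drawn from it with replacement.
    """
    shape = mpm.shape
    if any(patch_size > s for s in shape):
        raise ValueError(
            f"patch size {patch_size} exceeds volume shape {shape}"
        )
    origin = tuple(
        int(rng.integers(0, s - patch_size + 1)) for s in shape
    )
    sub = mpm.crop(origin, patch_size)
    label_patch = labels.crop(origin, patch_size)

    images, phys, params = [], [], []
    for _ in range(n):
        if params_list is not None:
            p = params_list[int(rng.integers(0, len(params_list)))]
        else:
            p = sample_params(ranges, rng)
        img = simulate(sub, p, magnitude=magnitude)
        images.append(img.intensities)
        phys.append(physics_vector(p).as_array())
        params.append(p)
    return TrainingBatch(
        images=np.stack(images),
        physics=np.stack(phys),
        params=params,
        labels=label_patch,
        subject_id=mpm.subject_id,
        patch_origin=origin,
    )


def _polynomial_field(shape, order: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random polynomial over the unit cube, zero mean-ish."""
    grids = [np.linspace(-1, 1, s) for s in shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    out = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                coef = rng.normal(0, 1.0 / (1 + i + j + k))
                out += coef * x**i * y**j * z**k
    return out


def apply_bias_field(
    image: np.ndarray,
    rng: np.random.Generator,
    amplitude: float = 0.3,
    order: int = 3,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicative smooth polynomial field with mean 1 over the mask.

    The raw polynomial is scaled to max |deviation| = amplitude ``a`` and
    then recentred so its in-mask mean is 1; the per-voxel ratio out/in
    is therefore within [(1-a)/(1+a), (1+a)/(1-a)].
    """
    image = np.asarray(image, dtype=np.float64)
    if amplitude == 0:
        return image.copy()
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    f = _polynomial_field(image.shape, order, rng)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * amplitude
    field = 1.0 + f
    field = field / field[mask].mean()
    return image * field


def add_noise(
    image: np.ndarray,
    rng: np.random.Generator,
    sd: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Additive zero-mean Gaussian noise, in-mask only.

    ``sd`` is a fraction of the mean absolute in-mask intensity.
    """
    image = np.asarray(image, dtype=np.float64)
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return image.copy()
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    ref = np.abs(image[mask]).mean() if mask.any() else 0.0
    noise = rng.normal(0.0, sd * ref, size=image.shape)
    return np.where(mask, image + noise, image)


def _sample_affine(config: AugmentationConfig, rng, shape):
    """Random rotation/scale/translation matrix about the patch centre."""
    angles = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg, 3))
    rots = []
    for axis, a in enumerate(angles):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
        rots.append(m)
    mat = rots[0] @ rots[1] @ rots[2]
    scale = rng.uniform(*config.scale_range)
    mat = mat * scale
    centre = (np.asarray(shape) - 1) / 2.0
    shift = rng.uniform(-config.translation_vox, config.translation_vox, 3)
    # output coord -> input coord: inverse mapping
    inv = np.linalg.inv(mat)
    offset = centre - inv @ (centre + shift)
    return inv, offset


def _sample_ffd(config: AugmentationConfig, rng, shape):
    """Dense displacement field from a coarse control grid; retries on
    fold-over (non-positive Jacobian along axes)."""
    if config.ffd_max_displacement_vox == 0:
        return np.zeros((3,) + tuple(shape))
    g = config.ffd_grid
    for _ in range(5):
        ctrl = rng.uniform(
            -config.ffd_max_displacement_vox,
            config.ffd_max_displacement_vox,
            size=(3, g, g, g),
        )
        disp = np.stack(
            [zoom(ctrl[a], np.asarray(shape) / g, order=3) for a in range(3)]
        )
        # crude fold-over check: forward differences of (x + u) must stay positive
        ok = True
        for a in range(3):
            d = np.diff(disp[a], axis=a)
            if (d <= -1.0).any():
                ok = False
                break
        if ok:
            return disp
    raise RuntimeError("could not sample a fold-over-free deformation in 5 tries")


def apply_spatial_augs(
    batch: TrainingBatch,
    rng: np.random.Generator,
    config: AugmentationConfig,
) -> TrainingBatch:
    """One shared spatial transform for all members and the label;
    per-member intensity corruptions (blur, bias field, noise)."""
    shape = batch.images.shape[1:]
    identity_spatial = (
        config.rotation_deg == 0
        and config.scale_range == (1.0, 1.0)
        and config.translation_vox == 0
        and config.ffd_max_displacement_vox == 0
    )
    if not identity_spatial:
        inv, offset = _sample_affine(config, rng, shape)
        disp = _sample_ffd(config, rng, shape)
        idx = np.indices(shape, dtype=np.float64)
        warped = np.einsum("ab,b...->a...", inv, idx) + offset.reshape(3, 1, 1, 1)
        coords = warped + disp

        def warp(vol, order=1):
            return map_coordinates(vol, coords, order=order, mode="nearest")

        images = np.stack([warp(im) for im in batch.images])
        lab = np.stack([warp(ch) for ch in batch.labels.responsibilities])
        lab = np.clip(lab, 0, None)
        lab /= np.clip(lab.sum(axis=0, keepdims=True), 1e-12, None)
        labels = SoftLabelMap(lab)
    else:
        images = batch.images.copy()
        labels = batch.labels

    out = []
    fg = labels.foreground_mask
    for im in images:
        blur = rng.uniform(*config.blur_sd_range)
        if blur > 0:
            im = gaussian_filter(im, blur)
        im = apply_bias_field(
            im, rng, config.bias_field_amplitude, config.bias_field_order, mask=fg
        )
        sd = rng.uniform(*config.noise_sd_range)
        im = add_noise(im, rng, sd, mask=fg)
        out.append(im)
    return TrainingBatch(
        images=np.stack(out),
        physics=batch.physics,
        params=batch.params,
        labels=labels,
        subject_id=batch.subject_id,
        patch_origin=batch.patch_origin,
    )
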