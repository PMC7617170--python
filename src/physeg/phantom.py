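"""Synthetic multi-parametric map (MPM) head phantoms and NIfTI I/O.

An MPM is a set of co-registered quantitative maps — the longitudinal
relaxation rate R1 (s^-1), the effective transverse relaxation rate R2*
(s^-1), and proton density PD (a.u.) — that describe intrinsic tissue
properties independently of any acquisition.  The phantom generator builds
a skull-stripped three-compartment head (a WM core inside a GM ribbon
inside a CSF shell, each a randomly deformed ellipsoid) and fills each
compartment with tissue values drawn from per-class Gaussians, so every
downstream stage (simulation, labelling, training, uncertainty) is testable
without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MPMVolume",
    "PhantomSpec",
    "TISSUE_CLASSES",
    "generate_phantom",
    "read_mpm",
    "write_volume",
]

#: Channel order used throughout the package (background is appended last
#: in soft label maps).
TISSUE_CLASSES = ("csf", "gm", "wm")

# Literature R1 statistics (s^-1) for the three tissue classes at 3T.
DEFAULT_R1_PARAMS = {
    "csf": (0.240, 0.030),
    "gm": (0.683, 0.080),
    "wm": (1.036, 0.080),
}

# R2* (s^-1) and PD (a.u.) per class are plausible constants chosen to
# produce realistic contrast; the label model never uses them.
DEFAULT_R2S_VALUES = {"csf": 1.0, "gm": 16.0, "wm": 21.0}
DEFAULT_PD_VALUES = {"csf": 1.0, "gm": 0.85, "wm": 0.70}


@dataclass
class MPMVolume:
    """Per-voxel quantitative maps plus intracranial mask and grid metadata.

    Invariants: all maps share one shape; ``r1 > 0``, ``r2s > 0`` and
    ``pd >= 0`` inside the mask; all maps are zero outside the mask.
    """

    r1: np.ndarray
    r2s: np.ndarray
    pd: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=np.float64)
        self.r2s = np.asarray(self.r2s, dtype=np.float64)
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        shapes = {self.r1.shape, self.r2s.shape, self.pd.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"MPM channels have mismatched shapes: {sorted(shapes)}")
        if self.r1.ndim != 3:
            raise ValueError("MPM maps must be 3-D")
        m = self.mask
        if m.any():
            if not (self.r1[m] > 0).all():
                raise ValueError("r1 must be positive inside the mask")
            if not (self.r2s[m] > 0).all():
                raise ValueError("r2s must be positive inside the mask")
            if not (self.pd[m] >= 0).all():
                raise ValueError("pd must be non-negative inside the mask")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.r1.shape

    def crop(self, origin: tuple[int, int, int], size: int) -> "MPMVolume":
        """Extract a cubic sub-volume (used for patch-restricted simulation)."""
        sl = tuple(slice(o, o + size) for o in origin)
        return replace(
            self,
            r1=self.r1[sl],
            r2s=self.r2s[sl],
            pd=self.pd[sl],
            mask=self.mask[sl],
        )


@dataclass
class PhantomSpec:
    """Geometry and tissue statistics for a synthetic MPM phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    #: outer semi-axis fractions (of half the grid) for CSF, GM, WM surfaces
    compartment_radii: tuple[float, float, float] = (0.88, 0.72, 0.5)
    #: amplitude of the random radial deformation of each surface (fraction)
    deformation_amplitude: float = 0.08
    tissue_r1_params: dict = field(default_factory=lambda: dict(DEFAULT_R1_PARAMS))
    tissue_r2s_values: dict = field(default_factory=lambda: dict(DEFAULT_R2S_VALUES))
    tissue_pd_values: dict = field(default_factory=lambda: dict(DEFAULT_PD_VALUES))
    #: Gaussian blur (voxels) applied to the one-hot labels to create
    #: partial-volume boundary voxels; 0 disables smoothing.
    boundary_smoothing_sigma: float = 1.0
    #: within-tissue spatial smoothing of the sampled R1 field (voxels)
    texture_smoothing_sigma: float = 1.0
    seed: int = 0
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom shape must be at least 8 voxels per axis")
        r = self.compartment_radii
        if not (r[0] > r[1] > r[2] > 0):
            raise ValueError("compartment radii must be strictly nested (CSF > GM > WM > 0)")
        for cls in TISSUE_CLASSES:
            mean, sd = self.tissue_r1_params[cls]
            if sd < 0:
                raise ValueError(f"negative R1 sd for class {cls!r}")
            if mean <= 0:
                raise ValueError(f"non-positive R1 mean for class {cls!r}")


def _deformed_radius(
    coords: np.ndarray, radii: np.ndarray, rng: np.random.Generator, amplitude: float
) -> np.ndarray:
    """Signed field: negative inside a randomly deformed ellipsoid."""
    # low-order spherical-harmonic-like perturbation from random cosines
    x, y, z = coords
    pert = np.zeros_like(x)
    for _ in range(3):
        k = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        pert += (
            np.cos(k[0] * np.pi * x + phase[0])
            * np.cos(k[1] * np.pi * y + phase[1])
            * np.cos(k[2] * np.pi * z + phase[2])
        )
    pert *= amplitude / 3.0
    r = np.sqrt((x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2)
    return r - (1.0 + pert)


def generate_phantom(spec: PhantomSpec):
    """Build an :class:`MPMVolume` and its generating ground-truth labels.

    The three tissue surfaces are nested deformed ellipsoids.  Within each
    compartment, R1 is drawn i.i.d. from the class Gaussian and then
    spatially smoothed (preserving the class mean); R2* and PD are class
    constants.  The generating soft labels are the (optionally blurred)
    one-hot compartment maps; blurring produces partial-volume voxels that
    emulate continuous tissue boundaries.

    Returns ``(mpm, labels)`` where ``labels`` is a
    :class:`physeg.labels.SoftLabelMap`.  Deterministic for a fixed seed.
    """
    from .labels import SoftLabelMap

    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    grids = [np.linspace(-1.0, 1.0, s) for s in shape]
    coords = np.meshgrid(*grids, indexing="ij")

    # per-axis semi-axes with mild anisotropy so phantoms are not spheres
    aniso = rng.uniform(0.9, 1.0, size=(3, 3))
    fields = []
    for i, frac in enumerate(spec.compartment_radii):
        radii = frac * aniso[i]
        fields.append(
            _deformed_radius(coords, radii, rng, spec.deformation_amplitude)
        )
    inside = [f < 0 for f in fields]  # CSF-outer, GM-outer, WM surfaces

    wm = inside[2]
    gm = inside[1] & ~wm
    csf = inside[0] & ~inside[1]
    for name, comp in zip(("wm", "gm", "csf"), (wm, gm, csf)):
        if not comp.any():
            raise ValueError(f"degenerate phantom geometry: empty {name} compartment")

    onehot = np.zeros((4,) + shape)  # CSF, GM, WM, background
    onehot[0] = csf
    onehot[1] = gm
    onehot[2] = wm
    onehot[3] = ~(csf | gm | wm)

    if spec.boundary_smoothing_sigma > 0:
        for c in range(4):
            onehot[c] = gaussian_filter(onehot[c], spec.boundary_smoothing_sigma)
        onehot /= onehot.sum(axis=0, keepdims=True)

    mask = onehot[3] < 0.5
    labels = np.where(mask[None], onehot, 0.0)
    labels[3] = np.where(mask, onehot[3], 1.0)
    labels /= labels.sum(axis=0, keepdims=True)

    # tissue parameter fields
    r1 = np.zeros(shape)
    r2s = np.zeros(shape)
    pd = np.zeros(shape)
    hard = {"csf": csf, "gm": gm, "wm": wm}
    for cls in TISSUE_CLASSES:
        mean, sd = spec.tissue_r1_params[cls]
        draw = rng.normal(mean, sd, size=shape)
        if spec.texture_smoothing_sigma > 0 and sd > 0:
            # smooth the fluctuation only, keeping the class mean exact
            draw = mean + gaussian_filter(draw - mean, spec.texture_smoothing_sigma)
        r1 = np.where(hard[cls], draw, r1)
        r2s = np.where(hard[cls], spec.tissue_r2s_values[cls], r2s)
        pd = np.where(hard[cls], spec.tissue_pd_values[cls], pd)

    # partial-volume blend of tissue parameters at smoothed boundaries
    if spec.boundary_smoothing_sigma > 0:
        w = labels[:3] / np.clip(labels[:3].sum(axis=0), 1e-12, None)
        means = {c: spec.tissue_r1_params[c][0] for c in TISSUE_CLASSES}
        blend_r1 = sum(w[i] * means[c] for i, c in enumerate(TISSUE_CLASSES))
        blend_r2s = sum(w[i] * spec.tissue_r2s_values[c] for i, c in enumerate(TISSUE_CLASSES))
        blend_pd = sum(w[i] * spec.tissue_pd_values[c] for i, c in enumerate(TISSUE_CLASSES))
        pure = csf | gm | wm
        boundary = mask & ~pure
        r1 = np.where(boundary, blend_r1, r1)
        r2s = np.where(boundary, blend_r2s, r2s)
        pd = np.where(boundary, blend_pd, pd)

    r1 = np.where(mask, np.clip(r1, 1e-3, None), 0.0)
    r2s = np.where(mask, np.clip(r2s, 1e-3, None), 0.0)
    pd = np.where(mask, np.clip(pd, 0.0, None), 0.0)

    mpm = MPMVolume(
        r1=r1, r2s=r2s, pd=pd, mask=mask, subject_id=spec.subject_id
    )
    return mpm, SoftLabelMap(responsibilities=labels, pure_mask=pure_masks(csf, gm, wm))


def pure_masks(csf: np.ndarray, gm: np.ndarray, wm: np.ndarray) -> np.ndarray:
    """Stack of the generating pure-tissue compartments (CSF, GM, WM)."""
    return np.stack([csf, gm, wm])


def write_volume(data: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a 3-D (or 4-D) map to a NIfTI-1 file."""
    data = np.asarray(data)
    if not np.isfinite(data).all():
        raise ValueError("refusing to write non-finite values to NIfTI")
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms(tuple(spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def _read_channel(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=np.float64), tuple(float(z) for z in zooms)


def read_mpm(
    r1_path, r2s_path, pd_path, mask_path=None, subject_id: str = "subject"
) -> MPMVolume:
    """Load an MPM from per-channel NIfTI files.

    The mask defaults to ``pd > 0`` when no mask file is given.  Channels
    with mismatched grids raise, naming the offending channels.
    """
    channels = {}
    spacings = {}
    for name, p in (("r1", r1_path), ("r2s", r2s_path), ("pd", pd_path)):
        channels[name], spacings[name] = _read_channel(p)
    shapes = {name: arr.shape for name, arr in channels.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"MPM channels have different grids: {shapes}")
    if mask_path is not None:
        mask, _ = _read_channel(mask_path)
        if mask.shape != channels["r1"].shape:
            raise ValueError(
                f"mask grid {mask.shape} does not match r1 grid {channels['r1'].shape}"
            )
        mask = mask > 0.5
    else:
        mask = channels["pd"] > 0
    for name in channels:
        channels[name] = np.where(mask, channels[name], 0.0)
    return MPMVolume(
        r1=channels["r1"],
        r2s=channels["r2s"],
        pd=channels["pd"],
        mask=mask,
        spacing=spacings["r1"],
        subject_id=subject_id,
    )


def write_mpm(mpm: MPMVolume, out_dir) -> dict:
    """Write all MPM channels and the mask; returns the path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, arr in (
        ("r1", mpm.r1),
        ("r2s", mpm.r2s),
        ("pd", mpm.pd),
        ("mask", mpm.mask.astype(np.float32)),
    ):
        p = os.path.join(out_dir, f"{mpm.subject_id}_{name}.nii.gz")
        write_volume(arr, p, mpm.spacing)
        paths[name] = p
    return paths
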