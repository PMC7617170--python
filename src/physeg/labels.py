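"""Physics Gold Standard (PGS) soft tissue labels.

Tissue labels are derived directly from the quantitative R1 map rather
than from any contrast-weighted image: each class (CSF, GM, WM) is
modelled as a Gaussian over R1, and a voxel's label is the posterior
responsibility of each class given its R1 value.  Because the labels are
functions of intrinsic tissue parameters only, they are constant across
every simulated contrast of a subject — the property the stratification
loss exploits.  Labels are soft (responsibilities, not categories), which
captures the continuous, partial-volume nature of tissue boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phantom import MPMVolume, TISSUE_CLASSES

logger = logging.getLogger(__name__)

__all__ = ["TissueClassParams", "SoftLabelMap", "pgs_labels", "hard_labels"]

#: Channel order of soft label maps.
LABEL_CHANNELS = ("csf", "gm", "wm", "background")


@dataclass
class TissueClassParams:
    """Per-class R1 Gaussians (s^-1) and prior weights.

    Defaults are the literature values for 3T: GM N(0.683, 0.080^2),
    WM N(1.036, 0.080^2), CSF N(0.240, 0.030^2), with equal priors.
    """

    means: dict = field(
        default_factory=lambda: {"csf": 0.240, "gm": 0.683, "wm": 1.036}
    )
    sds: dict = field(
        default_factory=lambda: {"csf": 0.030, "gm": 0.080, "wm": 0.080}
    )
    priors: dict = field(
        default_factory=lambda: {"csf": 1.0, "gm": 1.0, "wm": 1.0}
    )

    def __post_init__(self) -> None:
        for cls in TISSUE_CLASSES:
            if self.sds[cls] <= 0:
                raise ValueError(f"sd must be positive for class {cls!r}")
            if self.priors[cls] <= 0:
                raise ValueError(f"prior must be positive for class {cls!r}")


@dataclass
class SoftLabelMap:
    """4-channel responsibilities (CSF, GM, WM, background) summing to 1."""

    responsibilities: np.ndarray
    #: optional stack of the generating pure-tissue compartments (phantoms)
    pure_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.responsibilities, dtype=np.float64)
        if r.ndim != 4 or r.shape[0] != 4:
            raise ValueError("responsibilities must have shape (4, D, H, W)")
        if (r < -1e-9).any() or (r > 1 + 1e-9).any():
            raise ValueError("responsibilities must lie in [0, 1]")
        sums = r.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("responsibilities must sum to 1 at every voxel")
        self.responsibilities = r

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.responsibilities.shape[1:]

    @property
    def foreground_mask(self) -> np.ndarray:
        return self.responsibilities[3] < 0.5

    def crop(self, origin, size: int) -> "SoftLabelMap":
        sl = (slice(None),) + tuple(slice(o, o + size) for o in origin)
        pm = None if self.pure_mask is None else self.pure_mask[sl]
        return SoftLabelMap(self.responsibilities[sl], pure_mask=pm)

    def volumes(self) -> dict:
        """Soft class volumes (sum of responsibilities) for CSF/GM/WM."""
        return {
            cls: float(self.responsibilities[i].sum())
            for i, cls in enumerate(TISSUE_CLASSES)
        }


def pgs_labels(
    mpm: MPMVolume,
    params: TissueClassParams | None = None,
    em_refine: bool = False,
    em_iters: int = 20,
) -> SoftLabelMap:
    """Posterior tissue responsibilities from the R1 map.

    Inside the mask, the responsibility of class k at voxel x is

        pi_k N(r1(x); mu_k, sd_k^2) / sum_j pi_j N(r1(x); mu_j, sd_j^2)

    under the fixed literature Gaussians (no refitting by default; labels
    are then constant per subject and fully reproducible).  Outside the
    mask the background channel is exactly 1.

    With ``em_refine=True`` the class sds and priors are refined by EM on
    the in-mask R1 values, with the means frozen at their literature
    anchors.
    """
    if params is None:
        params = TissueClassParams()
    mask = mpm.mask
    r1 = mpm.r1

    mu = np.array([params.means[c] for c in TISSUE_CLASSES])
    sd = np.array([params.sds[c] for c in TISSUE_CLASSES])
    pi = np.array([params.priors[c] for c in TISSUE_CLASSES], dtype=np.float64)
    pi = pi / pi.sum()

    x = r1[mask][None, :]  # (1, V)
    if em_refine and mask.any():
        for _ in range(em_iters):
            resp = _responsibilities(x, mu, sd, pi)
            nk = resp.sum(axis=1) + 1e-12
            # means frozen at the literature anchors
            sd = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
            sd = np.clip(sd, 1e-4, None)
            pi = nk / nk.sum()

    resp = _responsibilities(x, mu, sd, pi)

    out = np.zeros((4,) + mpm.shape)
    for k in range(3):
        out[k][mask] = resp[k]
    out[3] = np.where(mask, 0.0, 1.0)
    return SoftLabelMap(out)


def _responsibilities(x, mu, sd, pi):
    """Stable posterior responsibilities of K Gaussians at points x (K,V)."""
    logp = (
        np.log(pi)[:, None]
        - np.log(sd)[:, None]
        - 0.5 * ((x - mu[:, None]) / sd[:, None]) ** 2
    )
    m = logp.max(axis=0, keepdims=True)
    w = np.exp(logp - m)
    tot = w.sum(axis=0, keepdims=True)
    underflow = ~np.isfinite(m[0]) | (tot[0] == 0)
    resp = w / np.clip(tot, 1e-300, None)
    if underflow.any():
        # all densities underflow: assign the nearest-mean class outright
        logger.warning(
            "%d voxels with underflowing class densities; assigning nearest mean",
            int(underflow.sum()),
        )
        nearest = np.argmin(np.abs(x - mu[:, None]), axis=0)
        for k in range(len(mu)):
            resp[k, underflow] = (nearest[underflow] == k).astype(float)
    return resp


def hard_labels(soft: SoftLabelMap) -> np.ndarray:
    """Categorical map by argmax; ties break to the lower channel index
    (CSF < GM < WM < background)."""
    return np.argmax(soft.responsibilities, axis=0)
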