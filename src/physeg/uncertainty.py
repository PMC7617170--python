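"""From segmentation samples to calibrated volumetric error bounds.

Epistemic uncertainty is sampled by Monte-Carlo dropout (T stochastic
forward passes); aleatoric by perturbing the task logits with the
predicted heteroscedastic noise scales.  A stack of T sampled probability
maps is reduced to *percentile volumes*: every voxel's T class
probabilities are sorted in ascending order, giving T voxelwise-sorted
prediction sets lambda_p whose voxel sums V_p form a non-decreasing
sequence of class volumes.  A monotone piecewise-linear calibration map,
fitted on validation subjects so that the quantile at which each true
volume falls inside its V_p sequence is uniformly distributed, converts
nominal percentiles into calibrated ones; calibrated intervals then
cover the truth at their nominal rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import TISSUE_CLASSES
from .nn.unet import PhysicsUNet3D, softmax_probs
from .simulate import physics_vector, simulate

__all__ = [
    "SampleStack",
    "PercentileVolumes",
    "CalibrationModel",
    "mc_sample",
    "het_sample",
    "percentile_volumes",
    "fit_calibration",
    "volume_interval",
    "uncertainty_grid",
]


@dataclass
class SampleStack:
    """T sampled probability maps, shape (T, C, D, H, W)."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 5:
            raise ValueError("samples must have shape (T, C, D, H, W)")
        if s.shape[0] < 2:
            raise ValueError("need T >= 2 samples for any interval")
        if (s < -1e-9).any() or (s > 1 + 1e-9).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(s.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("per-voxel class probabilities must sum to 1")
        self.samples = s

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return self.samples.shape[1]


def mc_sample(
    net: PhysicsUNet3D, image, physics, T: int, rng: np.random.Generator
) -> SampleStack:
    """T Monte-Carlo-dropout forward passes on one image."""
    if T < 2:
        raise ValueError("need T >= 2 samples")
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[None, None]
    pv = None
    if net.config.physics_len:
        pv = np.asarray(physics, dtype=np.float64).reshape(1, -1)
    out = []
    for _ in range(T):
        o = net.forward(image, pv, mode="mc-dropout", rng=rng)
        out.append(softmax_probs(o.logits)[0])
    return SampleStack(np.stack(out))


def het_sample(
    logits: np.ndarray, sigma: np.ndarray, T: int, rng: np.random.Generator
) -> SampleStack:
    """T draws of softmax(f + eps), eps ~ N(0, sigma^2)."""
    logits = np.asarray(logits, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    out = []
    for _ in range(T):
        eta = logits + sigma * rng.standard_normal(logits.shape)
        out.append(softmax_probs(eta[None], axis=1)[0])
    return SampleStack(np.stack(out))


@dataclass
class PercentileVolumes:
    """Sorted per-percentile class volumes, shape (C, T), non-decreasing
    along the percentile axis."""

    volumes: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=np.float64)
        if (np.diff(v, axis=1) < -1e-9).any():
            raise ValueError("percentile volumes must be non-decreasing")
        self.volumes = v

    @property
    def T(self) -> int:
        return self.volumes.shape[1]

    def quantile_of(self, true_volume: float, class_idx: int) -> float:
        """Quantile (0..1) at which a volume falls in the V_p sequence,
        by linear interpolation; clamped to [0, 1] outside the range."""
        v = self.volumes[class_idx]
        grid = (np.arange(self.T) + 0.5) / self.T
        if true_volume <= v[0]:
            return 0.0
        if true_volume >= v[-1]:
            return 1.0
        return float(np.interp(true_volume, v, grid))

    def volume_at(self, p, class_idx: int):
        """V at nominal percentile(s) p in [0, 1], linearly interpolated."""
        v = self.volumes[class_idx]
        grid = (np.arange(self.T) + 0.5) / self.T
        return np.interp(p, grid, v)


def percentile_volumes(stack: SampleStack) -> PercentileVolumes:
    """Voxelwise ascending sort across samples, then sum over voxels."""
    s = np.sort(stack.samples, axis=0)  # sort each voxel across T
    v = s.sum(axis=(2, 3, 4)).T  # (C, T)
    return PercentileVolumes(v)


@dataclass
class CalibrationModel:
    """Monotone piecewise-linear nominal->calibrated percentile maps,
    per class; endpoints pinned at 0 and 1."""

    knots: np.ndarray  # (K,) nominal percentiles, includes 0 and 1
    values: np.ndarray  # (C, K) calibrated percentiles

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if not (k[0] == 0 and k[-1] == 1):
            raise ValueError("knots must span [0, 1]")
        if (np.diff(v, axis=1) < -1e-12).any():
            raise ValueError("calibration map must be monotone")
        if not (np.allclose(v[:, 0], 0) and np.allclose(v[:, -1], 1)):
            raise ValueError("calibration must pin 0 -> 0 and 1 -> 1")
        self.knots, self.values = k, v

    def __call__(self, p, class_idx: int):
        return np.interp(p, self.knots, self.values[class_idx])

    @classmethod
    def identity(cls, n_classes: int = len(TISSUE_CLASSES)) -> "CalibrationModel":
        k = np.array([0.0, 1.0])
        return cls(k, np.tile(k, (n_classes, 1)))

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(np.asarray(d["knots"]), np.asarray(d["values"]))


def fit_calibration(
    percentiles_per_subject,
    true_volumes,
    n_knots: int = 7,
) -> CalibrationModel:
    """Fit the percentile calibration on validation subjects.

    ``percentiles_per_subject``: list of :class:`PercentileVolumes`;
    ``true_volumes``: matching list of per-class true volumes (C,).  For
    each subject and class the true volume's quantile within the V_p
    sequence is located; the map sends each nominal percentile p to the
    empirical quantile function of these values (least-squares
    piecewise-linear on the QQ curve, isotonic-projected, endpoints
    pinned), so that mapped percentiles are uniformly covered.
    """
    pvs = list(percentiles_per_subject)
    if len(pvs) < 3:
        raise ValueError("calibration needs at least 3 validation subjects")
    n_classes = pvs[0].volumes.shape[0]
    knots = np.linspace(0, 1, n_knots)
    values = np.empty((n_classes, n_knots))
    for c in range(n_classes):
        q = []
        for pv, tv in zip(pvs, true_volumes):
            tvc = np.asarray(tv, dtype=np.float64)[c]
            if tvc < pv.volumes[c][0] or tvc > pv.volumes[c][-1]:
                warnings.warn(
                    "true volume outside the sampled percentile range; "
                    "quantile clamped"
                )
            q.append(pv.quantile_of(tvc, c))
        q = np.sort(np.asarray(q))
        # empirical QQ curve: uniform plotting positions -> observed quantiles
        pp = (np.arange(len(q)) + 0.5) / len(q)
        # target: for nominal percentile p return the empirical quantile of q
        vals = np.interp(knots, pp, q, left=0.0, right=1.0)
        vals[0], vals[-1] = 0.0, 1.0
        vals = np.maximum.accumulate(vals)
        vals = np.clip(vals, 0.0, 1.0)
        values[c] = vals
    return CalibrationModel(knots, values)


def volume_interval(
    stack_or_pv,
    calibration: CalibrationModel | None = None,
    level: float = 0.5,
) -> np.ndarray:
    """Calibrated [(1-level)/2, (1+level)/2] percentile volumes per class.

    Default level 0.5 is the interquartile range.  Returns (C, 2).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pv = (
        stack_or_pv
        if isinstance(stack_or_pv, PercentileVolumes)
        else percentile_volumes(stack_or_pv)
    )
    n_classes = pv.volumes.shape[0]
    if calibration is None:
        calibration = CalibrationModel.identity(n_classes)
    lo_n, hi_n = (1 - level) / 2, (1 + level) / 2
    out = np.empty((n_classes, 2))
    for c in range(n_classes):
        lo = calibration(lo_n, c)
        hi = calibration(hi_n, c)
        out[c] = (pv.volume_at(lo, c), pv.volume_at(hi, c))
    return out


def uncertainty_grid(
    net: PhysicsUNet3D,
    mpm,
    grid: dict,
    T: int,
    rng: np.random.Generator,
    calibration: CalibrationModel | None = None,
    sequence: str = "mprage",
    level: float = 0.5,
):
    """Mean volume and calibrated interval width per tissue over a
    parameter grid.

    Returns a tidy ``pandas.DataFrame`` with one row per (grid point,
    tissue): the sampled mean soft volume, the calibrated interval
    bounds, the width, and its log (for contouring).
    """
    import itertools

    import pandas as pd

    names = list(grid)
    values = [np.atleast_1d(grid[n]) for n in names]
    if not names or any(len(v) == 0 for v in values):
        raise ValueError("empty parameter grid")
    rows = []
    from .simulate import MPRAGEParams, SPGRParams

    for combo in itertools.product(*values):
        kw = dict(zip(names, (float(c) for c in combo)))
        if sequence == "mprage":
            p = MPRAGEParams(ti=kw["ti_ms"] / 1000.0, ptd=kw["ptd_ms"] / 1000.0)
        else:
            p = SPGRParams(
                tr=kw["tr_ms"] / 1000.0, te=kw["te_ms"] / 1000.0, fa=kw["fa_deg"]
            )
        img = simulate(mpm, p)
        stack = mc_sample(net, img.intensities, physics_vector(p).as_array(), T, rng)
        pv = percentile_volumes(stack)
        iv = volume_interval(pv, calibration, level=level)
        mean_vols = stack.samples.sum(axis=(2, 3, 4)).mean(axis=0)
        for i, cls in enumerate(TISSUE_CLASSES):
            width = float(iv[i, 1] - iv[i, 0])
            rows.append(
                {
                    **kw,
                    "tissue": cls,
                    "mean_volume": float(mean_vols[i]),
                    "lo": float(iv[i, 0]),
                    "hi": float(iv[i, 1]),
                    "width": width,
                    "log_width": float(np.log(max(width, 1e-12))),
                }
            )
    return pd.DataFrame(rows)
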