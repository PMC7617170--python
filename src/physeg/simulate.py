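"""Closed-form static-equation simulation of MPRAGE and SPGR contrasts.

The static equations approximate the steady-state signal of a voxel from
its intrinsic parameters (T1 = 1/R1, T2* = 1/R2*, PD) and the sequence
parameters, ignoring local MRI dynamics (no Bloch simulation, no k-space
or readout effects).  For an inversion-prepared MPRAGE sequence,

    b_M(x) = G_S PD(x) (1 - 2 e^{-TI/T1(x)} / (1 + e^{-TR/T1(x)})),

with TR = TI + TD + tau = TI + pTD, and for a spoiled gradient echo
(SPGR),

    b_S(x) = G_S PD(x) sin(theta)
             (1 - e^{-TR/T1}) / (1 - cos(theta) e^{-TR/T1}) e^{-TE/T2*}.

All times are SI seconds internally; flip angles are degrees at the
interface and radians in the physics vector.  The MPRAGE signal is signed
(it is negative for inversion times short of the tissue null point);
``magnitude=True`` mimics a magnitude reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .phantom import MPMVolume

__all__ = [
    "MPRAGEParams",
    "SPGRParams",
    "ParamRanges",
    "PhysicsVector",
    "SimulatedImage",
    "mprage_signal",
    "spgr_signal",
    "sample_params",
    "physics_vector",
    "simulation_grid",
]


@dataclass(frozen=True)
class MPRAGEParams:
    """MPRAGE acquisition parameters (seconds).

    Either give ``ptd`` (pseudo delay, the sum of the delay time TD and
    the echo-spacing time tau) or ``tr`` directly; the other is derived
    from the exact identity ``tr = ti + ptd``.
    """

    ti: float
    ptd: float | None = None
    tr: float | None = None
    gs: float = 1.0

    def __post_init__(self) -> None:
        if self.ti <= 0:
            raise ValueError("ti must be positive")
        if self.gs <= 0:
            raise ValueError("gs must be positive")
        if self.ptd is None and self.tr is None:
            raise ValueError("give either ptd or tr")
        if self.ptd is None:
            object.__setattr__(self, "ptd", self.tr - self.ti)
        if self.tr is None:
            object.__setattr__(self, "tr", self.ti + self.ptd)
        if abs(self.tr - (self.ti + self.ptd)) > 1e-12 * max(1.0, self.tr):
            raise ValueError("tr must equal ti + ptd exactly")
        if self.ptd < 0:
            raise ValueError("tr must be >= ti (ptd >= 0)")

    @classmethod
    def from_times(cls, ti: float, td: float, tau: float, gs: float = 1.0):
        """(TI, TD, tau) parameterisation; pTD = TD + tau."""
        return cls(ti=ti, ptd=td + tau, gs=gs)

    @property
    def sequence(self) -> str:
        return "mprage"


@dataclass(frozen=True)
class SPGRParams:
    """SPGR acquisition parameters (seconds; flip angle in degrees)."""

    tr: float
    te: float
    fa: float
    gs: float = 1.0

    def __post_init__(self) -> None:
        if not self.tr > self.te > 0:
            raise ValueError("require tr > te > 0")
        if not 0 < self.fa <= 90:
            raise ValueError("flip angle must lie in (0, 90] degrees")
        if self.gs <= 0:
            raise ValueError("gs must be positive")

    @property
    def sequence(self) -> str:
        return "spgr"


# Parameter ranges as printed in milliseconds / degrees, converted to SI
# at the ParamRanges interface.
MPRAGE_TRAIN_RANGES_MS = {"ti": (600.0, 1200.0), "ptd": (500.0, 1600.0)}
MPRAGE_OOD_TI_MS = (100.0, 2000.0)
SPGR_TRAIN_RANGES = {"tr": (15.0, 100.0), "te": (4.0, 10.0), "fa": (15.0, 75.0)}
SPGR_OOD_RANGES = {"tr": (10.0, 200.0), "te": (2.0, 20.0), "fa": (5.0, 90.0)}
MPRAGE_GRID_RANGES_MS = {"ti": (400.0, 2000.0), "ptd": (200.0, 2000.0)}


@dataclass(frozen=True)
class ParamRanges:
    """Closed intervals per free parameter, sampled uniformly.

    Times are given in milliseconds (as conventionally printed) and
    converted to seconds internally; flip angles stay in degrees.  For
    MPRAGE the free parameters are ``ti`` and ``ptd``; TR is always
    derived as TI + pTD.
    """

    sequence: str
    ti_ms: tuple[float, float] | None = None
    ptd_ms: tuple[float, float] | None = None
    tr_ms: tuple[float, float] | None = None
    te_ms: tuple[float, float] | None = None
    fa_deg: tuple[float, float] | None = None
    gs: float = 1.0

    def __post_init__(self) -> None:
        if self.sequence not in ("mprage", "spgr"):
            raise ValueError("sequence must be 'mprage' or 'spgr'")
        if self.sequence == "mprage":
            if self.ti_ms is None or self.ptd_ms is None:
                raise ValueError("MPRAGE ranges require ti_ms and ptd_ms")
            intervals = {"ti": self.ti_ms, "ptd": self.ptd_ms}
        else:
            if None in (self.tr_ms, self.te_ms, self.fa_deg):
                raise ValueError("SPGR ranges require tr_ms, te_ms and fa_deg")
            intervals = {"tr": self.tr_ms, "te": self.te_ms, "fa": self.fa_deg}
        for name, (lo, hi) in intervals.items():
            if lo > hi:
                raise ValueError(f"range for {name!r} has lower > upper")

    @classmethod
    def mprage_training(cls) -> "ParamRanges":
        """Training ranges: TI 600-1200 ms, pTD 500-1600 ms (TR 1100-2800 ms)."""
        return cls(sequence="mprage", ti_ms=MPRAGE_TRAIN_RANGES_MS["ti"],
                   ptd_ms=MPRAGE_TRAIN_RANGES_MS["ptd"])

    @classmethod
    def spgr_training(cls) -> "ParamRanges":
        """Training ranges: TR 15-100 ms, TE 4-10 ms, FA 15-75 deg."""
        return cls(sequence="spgr", tr_ms=SPGR_TRAIN_RANGES["tr"],
                   te_ms=SPGR_TRAIN_RANGES["te"], fa_deg=SPGR_TRAIN_RANGES["fa"])


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def sample_params(ranges: ParamRanges, rng: np.random.Generator):
    """Draw one parameter set, each free parameter independently uniform."""
    if ranges.sequence == "mprage":
        ti = _uniform(rng, *ranges.ti_ms) / 1000.0
        ptd = _uniform(rng, *ranges.ptd_ms) / 1000.0
        return MPRAGEParams(ti=ti, ptd=ptd, gs=ranges.gs)
    tr = _uniform(rng, *ranges.tr_ms) / 1000.0
    te = _uniform(rng, *ranges.te_ms) / 1000.0
    fa = _uniform(rng, *ranges.fa_deg)
    return SPGRParams(tr=tr, te=te, fa=fa, gs=ranges.gs)


@dataclass(frozen=True)
class PhysicsVector:
    """Encoded acquisition conditioning vector fed to the physics branch.

    MPRAGE: (TR, TI, e^-TR, e^-TI); SPGR: (TR, TE, FA_rad, e^-TR, e^-TE,
    sin FA).  Times in seconds; no further scaling.
    """

    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) not in (4, 6):
            raise ValueError("physics vector must have length 4 or 6")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)


def physics_vector(p) -> PhysicsVector:
    """Encode parameters for the network's physics branch."""
    if isinstance(p, MPRAGEParams):
        return PhysicsVector(
            (p.tr, p.ti, float(np.exp(-p.tr)), float(np.exp(-p.ti)))
        )
    if isinstance(p, SPGRParams):
        fa_rad = float(np.deg2rad(p.fa))
        return PhysicsVector(
            (
                p.tr,
                p.te,
                fa_rad,
                float(np.exp(-p.tr)),
                float(np.exp(-p.te)),
                float(np.sin(fa_rad)),
            )
        )
    raise TypeError(f"unsupported parameter type {type(p).__name__}")


@dataclass
class SimulatedImage:
    """A simulated contrast volume tagged with its parameters."""

    intensities: np.ndarray
    params: object
    subject_id: str = "subject"


def mprage_signal(
    mpm: MPMVolume, p: MPRAGEParams, magnitude: bool = False
) -> SimulatedImage:
    """Voxelwise MPRAGE static signal; zero outside the mask."""
    mask = mpm.mask
    if mask.any() and not (mpm.r1[mask] > 0).all():
        raise ValueError("non-positive R1 (infinite T1) inside mask")
    r1 = np.where(mask, mpm.r1, 1.0)  # placeholder outside mask
    sig = p.gs * mpm.pd * (
        1.0 - 2.0 * np.exp(-p.ti * r1) / (1.0 + np.exp(-p.tr * r1))
    )
    if magnitude:
        sig = np.abs(sig)
    sig = np.where(mask, sig, 0.0)
    return SimulatedImage(sig, p, mpm.subject_id)


def spgr_signal(mpm: MPMVolume, p: SPGRParams) -> SimulatedImage:
    """Voxelwise SPGR static signal; zero outside the mask."""
    mask = mpm.mask
    if mask.any():
        if not (mpm.r1[mask] > 0).all():
            raise ValueError("non-positive R1 inside mask")
        if not (mpm.r2s[mask] > 0).all():
            raise ValueError("non-positive R2* inside mask")
    r1 = np.where(mask, mpm.r1, 1.0)
    r2s = np.where(mask, mpm.r2s, 1.0)
    fa = np.deg2rad(p.fa)
    e1 = np.exp(-p.tr * r1)
    denom = 1.0 - np.cos(fa) * e1
    # for fa in (0, 90] and e1 in (0, 1) the denominator is positive
    sig = (
        p.gs
        * mpm.pd
        * np.sin(fa)
        * (1.0 - e1)
        / denom
        * np.exp(-p.te * r2s)
    )
    sig = np.where(mask, sig, 0.0)
    return SimulatedImage(sig, p, mpm.subject_id)


def simulate(mpm: MPMVolume, p, magnitude: bool = False) -> SimulatedImage:
    """Dispatch on parameter type."""
    if isinstance(p, MPRAGEParams):
        return mprage_signal(mpm, p, magnitude=magnitude)
    if isinstance(p, SPGRParams):
        return spgr_signal(mpm, p)
    raise TypeError(f"unsupported parameter type {type(p).__name__}")


def simulation_grid(mpm: MPMVolume, grid: dict, sequence: str = "mprage"):
    """Lazily yield one SimulatedImage per Cartesian grid point.

    ``grid`` maps parameter names (``ti_ms``/``ptd_ms`` for MPRAGE;
    ``tr_ms``/``te_ms``/``fa_deg`` for SPGR) to value lists in ms/deg.
    """
    names = list(grid)
    values = [np.atleast_1d(grid[n]) for n in names]
    if any(len(v) == 0 for v in values) or not names:
        raise ValueError("empty simulation grid")
    for combo in itertools.product(*values):
        kw = dict(zip(names, (float(c) for c in combo)))
        if sequence == "mprage":
            p = MPRAGEParams(ti=kw["ti_ms"] / 1000.0, ptd=kw["ptd_ms"] / 1000.0)
        elif sequence == "spgr":
            p = SPGRParams(
                tr=kw["tr_ms"] / 1000.0, te=kw["te_ms"] / 1000.0, fa=kw["fa_deg"]
            )
        else:
            raise ValueError(f"unknown sequence {sequence!r}")
        yield simulate(mpm, p)
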