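"""Synthetic multiparametric MR phantoms for hyperacute stroke timing.

Generates pre-registered, bias-free 3D volumes with three compartments
(nonischemic tissue, CSF, ischemic lesion) on a symmetric axial grid, plus
forward-simulated signal volumes: a multi-echo T2 train, a multi-b-value
diffusion series, and an optional FLAIR image.  The lesion carries a
depressed ADC and a T2 that grows linearly with time from symptom onset,
which is the statistical structure the downstream timing analysis relies on.

Conventions
-----------
* axis 0 is left/right; the mid-sagittal plane sits at index (nx - 1) / 2
* voxel indexing is 0-based; masks are voxel-center based
* ADC is expressed in um^2/ms, b values in s/mm^2, times in ms,
  onset times in minutes
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .qmaps import DiffusionSet, EchoSeries

__all__ = [
    "AcquisitionParams",
    "TissueParams",
    "PhantomSpec",
    "VirtualPatient",
    "BRISTOL",
    "GLASGOW",
    "OXFORD",
    "make_phantom",
    "simulate_echo_series",
    "simulate_diffusion",
    "simulate_flair",
    "make_cohort",
    "default_onset_sampler",
    "subcohort_onset_sampler",
    "WINDOW_MINUTES",
]

#: thrombolysis eligibility boundary (4.5 h) in minutes
WINDOW_MINUTES = 270.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings for one site-style protocol.

    ``b_values`` lists every acquired diffusion volume's b value, repeats
    encoding multiplicity (must include at least one b = 0).  FLAIR fields
    may all be None for protocols without a FLAIR scan.
    """

    echo_times: tuple[float, ...]  # ms, strictly increasing
    b_values: tuple[float, ...]  # s/mm^2, with multiplicity
    n_directions: int
    t2w_TR: float = 3000.0  # ms
    flair_TI: float | None = None  # ms
    flair_TR: float | None = None  # ms
    flair_TE: float | None = None  # ms

    def __post_init__(self) -> None:
        te = self.echo_times
        if len(te) < 1 or any(t <= 0 for t in te):
            raise ValueError("echo_times must be positive")
        if any(b >= a for a, b in zip(te[1:], te[:-1])):
            raise ValueError("echo_times must be strictly increasing")
        if 0 not in self.b_values:
            raise ValueError("b_values must include 0")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b_values must be nonnegative")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.flair_TI is not None:
            if self.flair_TR is None or self.flair_TE is None:
                raise ValueError("FLAIR needs TI, TR and TE together")
            if not self.flair_TI < self.flair_TR:
                raise ValueError("flair_TI must be < flair_TR")

    @property
    def has_flair(self) -> bool:
        return self.flair_TI is not None

    @property
    def b_nonzero(self) -> float:
        bs = sorted({b for b in self.b_values if b > 0})
        if len(bs) != 1:
            raise ValueError("expected exactly one nonzero b value")
        return bs[0]


# Site-style presets (3T): multi-echo TEs, diffusion scheme and FLAIR timing.
BRISTOL = AcquisitionParams(
    echo_times=(20.0, 40.0, 60.0, 80.0, 100.0),
    b_values=(0.0, 1000.0, 1000.0, 1000.0),
    n_directions=3,
    t2w_TR=3000.0,
)
GLASGOW = AcquisitionParams(
    echo_times=(9.5, 66.0, 123.0),
    b_values=(0.0,) * 3 + (1000.0,) * 20,
    n_directions=20,
    t2w_TR=12500.0,
    flair_TI=2500.0,
    flair_TR=10000.0,
    flair_TE=93.0,
)
OXFORD = AcquisitionParams(
    echo_times=(7.7, 77.0, 177.0),
    b_values=(0.0, 1000.0, 1000.0, 1000.0),
    n_directions=3,
    t2w_TR=12000.0,
    flair_TI=2500.0,
    flair_TR=9000.0,
    flair_TE=96.0,
)


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment ground-truth parameters."""

    adc: float  # um^2/ms
    t2: float  # ms
    pd: float  # proton density, arbitrary units
    t1: float  # ms (used only by the FLAIR forward model)

    def __post_init__(self) -> None:
        if self.adc <= 0 or self.t2 <= 0 or self.t1 <= 0:
            raise ValueError("ADC, T2 and T1 must all be > 0")
        if self.pd < 0:
            raise ValueError("proton density must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and noise model of a virtual head.

    The lesion is an ellipsoid that must lie entirely within one hemisphere
    (bilateral lesions are excluded from the analysis).  Lesion T2 grows
    linearly with onset time t: T2(t) = t2_baseline * (1 + slope * t); the
    default slope is a calibration choice, since no human growth rate is
    established.  Noise sigma is expressed as a fraction of tissue proton
    density; the default 3% reflects a realistic parenchymal SNR at 3T.
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: float = 2.0
    tissue: TissueParams = TissueParams(adc=0.77, t2=80.0, pd=100.0, t1=1200.0)
    csf: TissueParams = TissueParams(adc=3.0, t2=2000.0, pd=100.0, t1=4000.0)
    lesion: TissueParams = TissueParams(adc=0.50, t2=80.0, pd=100.0, t1=1400.0)
    t2_slope_per_min: float = 6.0e-4  # fractional lesion T2 growth per minute
    lesion_center_vox: tuple[float, float, float] = (13.0, 30.0, 12.0)
    lesion_semiaxes_vox: tuple[float, float, float] = (6.5, 5.5, 4.5)
    noise_sigma_rel: float = 0.03  # fraction of tissue PD
    noise_model: str = "rician"  # or "gaussian" (debugging)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be a 3D grid of at least 4 voxels per axis")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.t2_slope_per_min < 0:
            raise ValueError("t2_slope_per_min must be >= 0")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def sigma(self) -> float:
        """Absolute noise sigma in signal units."""
        return self.noise_sigma_rel * self.tissue.pd

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0


@dataclass
class VirtualPatient:
    """Ground truth for one simulated patient.

    Holds the parameter maps the forward models sample from, the planted
    lesion mask, and the true onset time.  Signal volumes are produced on
    demand by the ``simulate_*`` functions.
    """

    onset_minutes: float
    adc: np.ndarray  # um^2/ms
    t2: np.ndarray  # ms
    pd: np.ndarray
    t1: np.ndarray  # ms
    lesion_mask: np.ndarray  # bool
    brain_mask: np.ndarray  # bool
    spec: PhantomSpec
    acquisition: AcquisitionParams | None = None

    def __post_init__(self) -> None:
        if self.onset_minutes <= 0:
            raise ValueError("onset_minutes must be > 0")
        shapes = {m.shape for m in (self.adc, self.t2, self.pd, self.t1,
                                    self.lesion_mask, self.brain_mask)}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one grid")


def _ellipsoid_mask(shape: Sequence[int],
                    center: Sequence[float],
                    semiaxes: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def make_phantom(spec: PhantomSpec, onset_minutes: float) -> VirtualPatient:
    """Build ground-truth parameter maps for one virtual patient.

    Lesion voxels take the lesion ADC and the time-scaled lesion T2;
    everything else in the brain is nonischemic tissue except two
    midline-symmetric ventricle-like CSF compartments.

    Raises
    ------
    ValueError
        If the lesion ellipsoid extends outside the grid or crosses the
        mid-sagittal plane (bilateral lesions are an exclusion criterion).
    """
    if onset_minutes <= 0:
        raise ValueError("onset_minutes must be > 0")
    nx, ny, nz = spec.shape
    c = spec.lesion_center_vox
    a = spec.lesion_semiaxes_vox
    for dim, (ci, ai) in enumerate(zip(c, a)):
        if ci - ai < -0.5 or ci + ai > spec.shape[dim] - 0.5:
            raise ValueError("lesion extends outside the grid")
    midline = (nx - 1) / 2.0
    if c[0] - a[0] < midline < c[0] + a[0]:
        raise ValueError("lesion crosses the midline (bilateral lesions excluded)")

    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain = _ellipsoid_mask(spec.shape, center,
                            (0.45 * nx, 0.45 * ny, 0.45 * nz))
    # two lateral-ventricle-like CSF blobs, mirror-symmetric about midline
    vent_off = 0.125 * nx
    vent_ax = (0.04 * nx, 0.08 * ny, 0.12 * nz)
    csf = (_ellipsoid_mask(spec.shape, (center[0] - vent_off, center[1], center[2]), vent_ax)
           | _ellipsoid_mask(spec.shape, (center[0] + vent_off, center[1], center[2]), vent_ax))
    csf &= brain
    lesion = _ellipsoid_mask(spec.shape, c, a) & brain
    if not lesion.any():
        raise ValueError("lesion ellipsoid contains no voxels inside the brain")
    if (lesion & csf).any():
        raise ValueError("lesion overlaps the CSF compartment; move it")

    t2_lesion = spec.lesion.t2 * (1.0 + spec.t2_slope_per_min * onset_minutes)

    adc = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    pd = np.zeros(spec.shape)
    t1 = np.zeros(spec.shape)
    for mask, tp, t2val in (
        (brain & ~csf & ~lesion, spec.tissue, spec.tissue.t2),
        (csf, spec.csf, spec.csf.t2),
        (lesion, spec.lesion, t2_lesion),
    ):
        adc[mask] = tp.adc
        t2[mask] = t2val
        pd[mask] = tp.pd
        t1[mask] = tp.t1
    # avoid division by zero in forward models outside the head
    t2[~brain] = 1.0
    t1[~brain] = 1.0
    return VirtualPatient(onset_minutes=onset_minutes, adc=adc, t2=t2, pd=pd,
                          t1=t1, lesion_mask=lesion, brain_mask=brain, spec=spec)


def _add_noise(signal: np.ndarray, sigma: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return signal
    if model == "rician":
        # magnitude of a complex Gaussian channel pair
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    raise ValueError(f"unknown noise model {model!r}")


def _resolve_noise(patient: VirtualPatient, sigma: float | None,
                   rng: np.random.Generator | None):
    if sigma is None:
        sigma = patient.spec.sigma
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(patient.spec.seed)
    return sigma, rng


def simulate_echo_series(patient: VirtualPatient, params: AcquisitionParams,
                         sigma: float | None = None,
                         rng: np.random.Generator | None = None) -> EchoSeries:
    """Forward-simulate the multi-echo T2 train: S(TE) = PD exp(-TE/T2)."""
    sigma, rng = _resolve_noise(patient, sigma, rng)
    vols = np.stack([patient.pd * np.exp(-te / patient.t2)
                     for te in params.echo_times])
    vols = _add_noise(vols, sigma, patient.spec.noise_model, rng)
    return EchoSeries(volumes=vols, echo_times=tuple(params.echo_times))


def diffusion_directions(n: int) -> np.ndarray:
    """Deterministic set of n unit gradient directions.

    n = 3 returns the coordinate axes; larger n uses a Fibonacci sphere,
    which is non-collinear and well spread for tensor fitting.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    if n <= 3:
        return np.eye(3)[:n]
    idx = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * idx
    z = 1.0 - 2.0 * (idx + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_diffusion(patient: VirtualPatient, params: AcquisitionParams,
                       sigma: float | None = None,
                       rng: np.random.Generator | None = None,
                       anisotropy: tuple[float, float, float] | None = None,
                       ) -> DiffusionSet:
    """Forward-simulate the diffusion series.

    Isotropic by default: S_dir = S0 exp(-b ADC 1e-3), identical across
    directions.  With ``anisotropy`` = (f1, f2, f3) the voxel tensor becomes
    ADC * diag(f) / mean(f) in the grid frame, preserving mean diffusivity.
    Repeated b = 0 acquisitions are averaged into a single S0 volume, as a
    scanner would.
    """
    sigma, rng = _resolve_noise(patient, sigma, rng)
    b = params.b_nonzero
    n0 = sum(1 for bv in params.b_values if bv == 0)
    n_weighted = len(params.b_values) - n0
    ndir = params.n_directions
    if n_weighted % ndir != 0:
        raise ValueError("weighted multiplicity must be a multiple of n_directions")
    nav = n_weighted // ndir
    dirs = diffusion_directions(ndir)

    model = patient.spec.noise_model
    s0_true = patient.pd
    s0 = np.mean([_add_noise(s0_true, sigma, model, rng) for _ in range(n0)], axis=0)

    if anisotropy is None:
        gdg = np.ones(ndir)[:, None, None, None] * patient.adc
    else:
        f = np.asarray(anisotropy, dtype=float)
        f = f / f.mean()
        gdg = np.einsum("ki,i,ki->k", dirs, f, dirs)[:, None, None, None] * patient.adc
    true_dwis = s0_true * np.exp(-b * gdg * 1e-3)
    dwis = np.mean([_add_noise(true_dwis, sigma, model, rng) for _ in range(nav)], axis=0)
    return DiffusionSet(s0=s0, dwis=dwis, b=b, directions=dirs)


def simulate_flair(patient: VirtualPatient, params: AcquisitionParams,
                   sigma: float | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward-simulate a T2w FLAIR image.

    Inversion-recovery-attenuated T2-weighted signal:
    S = PD |1 - 2 exp(-TI/T1) + exp(-TR/T1)| exp(-TE/T2).  With TI near
    T1_csf ln 2 the CSF compartment is strongly suppressed.
    """
    if not params.has_flair:
        raise ValueError("acquisition has no FLAIR settings")
    if patient.t1 is None or not np.all(patient.t1[patient.brain_mask] > 0):
        raise ValueError("patient lacks T1 values required for FLAIR")
    sigma, rng = _resolve_noise(patient, sigma, rng)
    ti, tr, te = params.flair_TI, params.flair_TR, params.flair_TE
    ir = np.abs(1.0 - 2.0 * np.exp(-ti / patient.t1) + np.exp(-tr / patient.t1))
    sig = patient.pd * ir * np.exp(-te / patient.t2)
    return _add_noise(sig, sigma, patient.spec.noise_model, rng)


def default_onset_sampler(n: int, rng: np.random.Generator,
                          within_fraction: float = 16.0 / 35.0,
                          within_range: tuple[float, float] = (145.0, 265.0),
                          beyond_range: tuple[float, float] = (308.0, 569.0),
                          ) -> np.ndarray:
    """Sample onset times (minutes) emulating the full 35-patient cohort.

    Exactly round(n * within_fraction) patients fall within the 4.5-hour
    window; both strata are uniform over the observed onset ranges of the
    emulated cohort.  The returned order is shuffled.
    """
    n_within = int(round(n * within_fraction))
    onsets = np.concatenate([
        rng.uniform(*within_range, size=n_within),
        rng.uniform(*beyond_range, size=n - n_within),
    ])
    rng.shuffle(onsets)
    return onsets


def subcohort_onset_sampler(n: int, rng: np.random.Generator) -> np.ndarray:
    """Onset sampler emulating the 17-patient FLAIR subcohort (5 within, 12 beyond)."""
    return default_onset_sampler(
        n, rng, within_fraction=5.0 / 17.0,
        within_range=(148.0, 190.0), beyond_range=(334.0, 569.0))


def make_cohort(n: int = 35,
                spec: PhantomSpec | None = None,
                onset_sampler: Callable[[int, np.random.Generator], np.ndarray]
                | None = None,
                seed: int | None = None,
                acquisition: AcquisitionParams = BRISTOL,
                ) -> tuple[list[VirtualPatient], pd.DataFrame]:
    """Generate a reproducible cohort of virtual patients.

    Returns the patients (ground truth only; signals are simulated per
    patient downstream) and a cohort table skeleton with patient id, onset
    time and the within-window label (onset <= 270 min).
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if spec is None:
        spec = PhantomSpec()
    if seed is None:
        seed = spec.seed
    if onset_sampler is None:
        onset_sampler = default_onset_sampler
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    onsets = np.asarray(onset_sampler(n, rng), dtype=float)
    if len(onsets) != n or np.any(onsets <= 0):
        raise ValueError("onset sampler must yield n positive onset times")
    child_seeds = np.random.SeedSequence([seed, 0xA11CE]).generate_state(n) % (2**31)
    patients = []
    for i, onset in enumerate(onsets):
        pspec = replace(spec, seed=int(child_seeds[i]))
        patients.append(make_phantom(pspec, float(onset)))
        patients[-1].acquisition = acquisition
    skeleton = pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(n)],
        "onset_min": onsets,
        "label": (onsets <= WINDOW_MINUTES).astype(int),
    })
    return patients, skeleton
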