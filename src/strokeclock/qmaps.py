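"""Quantitative and weighted map computation from MR signal volumes.

Implements the map types the timing analysis consumes:

* ADC from a three-orthogonal-direction diffusion scheme,
  ADC = -ln(S1 S2 S3 / S0^3) / (3 b)
* mean diffusivity from >= 6 independent directions via a log-linear
  tensor least-squares fit (MD = trace / 3)
* effective DWI synthesized at b = 1000 s/mm^2, DWI = S0 exp(-1000 ADC 1e-3)
* echo-summed T2-weighted image (sum over the TE series)
* voxelwise mono-exponential T2, S(TE) = S0 exp(-TE/T2), by weighted
  log-linear least squares (weights proportional to signal^2) with an
  optional nonlinear Gauss-Newton refinement

Unit convention: ADC is stored in um^2/ms (= 1e-3 mm^2/s) and b in s/mm^2,
so every exponent is b * ADC * 1e-3.  Invalid voxels (nonpositive signals,
non-decaying series, T2 outside (0, 5000] ms) carry an explicit validity
mask rather than sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionSet",
    "EchoSeries",
    "QuantMapSet",
    "T2FitResult",
    "compute_adc_3dir",
    "compute_mean_diffusivity",
    "effective_dwi",
    "echo_sum_t2w",
    "fit_t2_map",
    "compute_quant_maps",
    "T2_MAX_MS",
    "DWI_SYNTHESIS_B",
]

T2_MAX_MS = 5000.0
#: effective DWI is synthesized at this b value (s/mm^2)
DWI_SYNTHESIS_B = 1000.0


@dataclass
class DiffusionSet:
    """One b = 0 volume plus per-direction volumes at a common nonzero b."""

    s0: np.ndarray
    dwis: np.ndarray  # (n_directions, *grid)
    b: float  # s/mm^2
    directions: np.ndarray | None = None  # (n_directions, 3) unit vectors

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.dwis = np.asarray(self.dwis, dtype=float)
        if self.b <= 0:
            raise ValueError("b must be > 0 for the weighted volumes")
        if self.dwis.ndim != self.s0.ndim + 1:
            raise ValueError("dwis must stack direction volumes on axis 0")
        if self.dwis.shape[1:] != self.s0.shape:
            raise ValueError("S0 and weighted volumes must share one grid")
        if self.directions is not None:
            self.directions = np.asarray(self.directions, dtype=float)
            if self.directions.shape != (self.n_directions, 3):
                raise ValueError("directions must be (n_directions, 3)")

    @property
    def n_directions(self) -> int:
        return self.dwis.shape[0]


@dataclass
class EchoSeries:
    """Signal volumes indexed by echo time."""

    volumes: np.ndarray  # (n_echoes, *grid)
    echo_times: tuple[float, ...]  # ms, strictly increasing

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        te = tuple(float(t) for t in self.echo_times)
        if len(te) < 1:
            raise ValueError("need at least one echo")
        if any(b >= a for a, b in zip(te[1:], te[:-1])) or te[0] < 0:
            raise ValueError("echo_times must be nonnegative and strictly increasing")
        if self.volumes.shape[0] != len(te):
            raise ValueError("one volume per echo time required")
        self.echo_times = te

    @property
    def n_echoes(self) -> int:
        return self.volumes.shape[0]


@dataclass
class T2FitResult:
    t2: np.ndarray  # ms
    s0: np.ndarray
    residual: np.ndarray  # per-voxel RMS residual in signal space
    valid: np.ndarray  # bool


@dataclass
class QuantMapSet:
    """Co-registered quantitative and weighted maps for one patient."""

    adc: np.ndarray  # um^2/ms
    dwi: np.ndarray
    t2w: np.ndarray
    t2: np.ndarray  # ms
    s0_fit: np.ndarray
    residual: np.ndarray
    valid: np.ndarray  # bool, ADC fit valid AND T2 fit valid
    flair: np.ndarray | None = None
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        grids = {m.shape for m in (self.adc, self.dwi, self.t2w, self.t2,
                                   self.s0_fit, self.residual, self.valid)}
        if self.flair is not None:
            grids.add(self.flair.shape)
        if len(grids) != 1:
            raise ValueError("all maps must share one grid")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def map_volume(self, name: str) -> np.ndarray | None:
        return {"adc": self.adc, "dwi": self.dwi, "t2w": self.t2w,
                "t2": self.t2, "flair": self.flair}[name]


def compute_adc_3dir(d: DiffusionSet) -> tuple[np.ndarray, np.ndarray]:
    """Orientation-independent ADC from three orthogonal directions.

    ADC = -ln(S1 S2 S3 / S0^3) / (3 b), converted to um^2/ms; equivalently
    the arithmetic mean of the three per-direction apparent diffusivities.

    Returns (adc, valid); voxels with any nonpositive signal are invalid.
    """
    if d.n_directions != 3:
        raise ValueError("the three-direction ADC formula needs exactly 3 directions")
    valid = (d.s0 > 0) & np.all(d.dwis > 0, axis=0)
    adc = np.zeros_like(d.s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(np.where(d.dwis > 0, d.dwis, 1.0)) - np.log(np.where(d.s0 > 0, d.s0, 1.0))
    adc_raw = -logs.sum(axis=0) / (3.0 * d.b) * 1e3
    adc[valid] = adc_raw[valid]
    return adc, valid


def compute_mean_diffusivity(d: DiffusionSet) -> tuple[np.ndarray, np.ndarray]:
    """Mean diffusivity from a log-linear tensor least-squares fit.

    Requires >= 6 non-collinear gradient directions; solves
    ln(S_i/S0) = -b g_i^T D g_i per voxel and returns MD = trace(D)/3
    in um^2/ms.  On isotropic input MD equals the scalar ADC.
    """
    if d.directions is None:
        raise ValueError("tensor fitting requires gradient directions")
    n = d.n_directions
    if n < 6:
        raise ValueError("tensor fitting needs at least 6 directions")
    g = d.directions
    design = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient direction set; directions are collinear/coplanar")
    valid = (d.s0 > 0) & np.all(d.dwis > 0, axis=0)
    flat = d.dwis.reshape(n, -1)
    s0 = d.s0.reshape(-1)
    y = np.zeros_like(flat)
    ok = valid.reshape(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y[:, ok] = -np.log(flat[:, ok] / s0[ok]) / d.b * 1e3
    tensor6 = np.linalg.pinv(design) @ y  # (6, nvox)
    md = tensor6[:3].mean(axis=0).reshape(d.s0.shape)
    md = np.where(valid, md, 0.0)
    return md, valid


def effective_dwi(s0: np.ndarray, adc: np.ndarray,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Synthesize a diffusion-weighted image at b = 1000 s/mm^2.

    DWI = S0 exp(-1000 * ADC * 1e-3) with ADC in um^2/ms.  Invalid-ADC
    voxels propagate as zero signal when a validity mask is given.
    """
    s0 = np.asarray(s0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    if s0.shape != adc.shape:
        raise ValueError("S0 and ADC grids must match")
    dwi = s0 * np.exp(-DWI_SYNTHESIS_B * adc * 1e-3)
    if valid is not None:
        dwi = np.where(valid, dwi, 0.0)
    return dwi


def echo_sum_t2w(e: EchoSeries) -> np.ndarray:
    """T2-weighted image as the voxelwise sum over the TE series."""
    return e.volumes.sum(axis=0)


def _loglinear_t2(e: EchoSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted log-linear fit of ln S = ln S0 - TE/T2, weights = S^2."""
    te = np.asarray(e.echo_times)
    vols = e.volumes
    positive = np.all(vols > 0, axis=0)
    s = np.where(vols > 0, vols, 1.0)
    w = s**2
    y = np.log(s)
    x = te.reshape(-1, *([1] * (vols.ndim - 1)))
    sw = w.sum(axis=0)
    sx = (w * x).sum(axis=0)
    sy = (w * y).sum(axis=0)
    sxx = (w * x * x).sum(axis=0)
    sxy = (w * x * y).sum(axis=0)
    denom = sw * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom != 0, (sw * sxy - sx * sy) / denom, 0.0)
        intercept = np.where(sw > 0, (sy - slope * sx) / sw, 0.0)
    return slope, intercept, positive


def _gauss_newton_refine(te: np.ndarray, vols: np.ndarray, s0: np.ndarray,
                         r2: np.ndarray, n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Gauss-Newton refinement of S0 exp(-TE R2) in signal space."""
    x = te.reshape(-1, *([1] * (vols.ndim - 1)))
    s0 = s0.copy()
    r2 = r2.copy()
    for _ in range(n_iter):
        model = s0 * np.exp(-x * r2)
        resid = vols - model
        j0 = model / np.where(s0 != 0, s0, 1.0)  # d model / d s0
        j1 = -x * model  # d model / d r2
        a00 = (j0 * j0).sum(axis=0)
        a01 = (j0 * j1).sum(axis=0)
        a11 = (j1 * j1).sum(axis=0)
        b0 = (j0 * resid).sum(axis=0)
        b1 = (j1 * resid).sum(axis=0)
        det = a00 * a11 - a01**2
        safe = np.abs(det) > 1e-30
        det = np.where(safe, det, 1.0)
        d_s0 = np.where(safe, (a11 * b0 - a01 * b1) / det, 0.0)
        d_r2 = np.where(safe, (a00 * b1 - a01 * b0) / det, 0.0)
        s0 = s0 + d_s0
        r2 = np.clip(r2 + d_r2, 1.0 / T2_MAX_MS / 50.0, None)
        s0 = np.clip(s0, 1e-12, None)
    return s0, r2


def fit_t2_map(e: EchoSeries, method: str = "loglin") -> T2FitResult:
    """Voxelwise mono-exponential T2 fit of an echo series.

    Parameters
    ----------
    e : EchoSeries
        At least two echoes.
    method : {"loglin", "nonlinear"}
        "loglin" is a signal^2-weighted log-linear least-squares fit;
        "nonlinear" refines it by Gauss-Newton in signal space.

    Voxels with any nonpositive echo, a non-decaying series, or fitted T2
    outside (0, 5000] ms are flagged invalid.
    """
    if method not in ("loglin", "nonlinear"):
        raise ValueError(f"unknown T2 fit method {method!r}")
    if e.n_echoes < 2:
        raise ValueError("T2 fitting needs at least two echoes")
    te = np.asarray(e.echo_times)
    slope, intercept, positive = _loglinear_t2(e)
    decaying = slope < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(decaying, -1.0 / np.where(slope != 0, slope, -1.0), 0.0)
    s0 = np.exp(intercept)
    if method == "nonlinear":
        r2 = np.where(decaying & positive, -slope, 1.0 / 100.0)
        s0_ref, r2_ref = _gauss_newton_refine(te, e.volumes, np.where(positive, s0, 1.0), r2)
        refine = positive & decaying
        s0 = np.where(refine, s0_ref, s0)
        t2 = np.where(refine, 1.0 / r2_ref, t2)
    valid = positive & decaying & (t2 > 0) & (t2 <= T2_MAX_MS)
    t2 = np.where(valid, t2, 0.0)
    s0 = np.where(valid, s0, 0.0)
    x = te.reshape(-1, *([1] * (e.volumes.ndim - 1)))
    with np.errstate(over="ignore", invalid="ignore"):
        model = s0 * np.exp(np.where(valid, -x / np.where(t2 > 0, t2, 1.0), 0.0))
    residual = np.sqrt(np.mean((e.volumes - model) ** 2, axis=0))
    residual = np.where(valid, residual, 0.0)
    return T2FitResult(t2=t2, s0=s0, residual=residual, valid=valid)


def compute_quant_maps(echoes: EchoSeries, diffusion: DiffusionSet,
                       flair: np.ndarray | None = None,
                       t2_method: str = "loglin",
                       voxel_size_mm: float = 1.0) -> QuantMapSet:
    """Assemble the full map set for one patient.

    The ADC route is chosen by the diffusion scheme: exactly 3 directions
    uses the closed-form three-direction formula, >= 6 uses the tensor
    mean-diffusivity fit.
    """
    if diffusion.n_directions == 3:
        adc, adc_valid = compute_adc_3dir(diffusion)
    elif diffusion.n_directions >= 6:
        adc, adc_valid = compute_mean_diffusivity(diffusion)
    else:
        raise ValueError("diffusion scheme must have 3 or >= 6 directions")
    fit = fit_t2_map(echoes, method=t2_method)
    return QuantMapSet(
        adc=adc,
        dwi=effective_dwi(diffusion.s0, adc, adc_valid),
        t2w=echo_sum_t2w(echoes),
        t2=fit.t2,
        s0_fit=fit.s0,
        residual=fit.residual,
        valid=adc_valid & fit.valid,
        flair=flair,
        voxel_size_mm=voxel_size_mm,
    )
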