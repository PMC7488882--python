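"""Ischemic VOI identification and the mirrored contralateral reference.

Ischemic voxels are defined on the quantitative maps only: an absolute ADC
window (default 0.30-0.55 um^2/ms), an adaptive rule requiring ADC to fall
more than one half-width-half-maximum (HWHM) below the median ADC of
nonischemic tissue, and T2 limits (30-200 ms) that suppress CSF.  The
candidate mask is refined to its principal connected component(s), and the
nonischemic reference VOI is the reflection of the ischemic VOI about the
mid-sagittal plane within each axial slice, with the same T2 limits
re-applied in place of manual CSF editing.

The adaptive rule is circular (nonischemic statistics require a lesion
estimate), resolved with a single bootstrap pass: the initial nonischemic
set is the brain minus all voxels passing the absolute ADC window, after
which the full rule is applied once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

__all__ = [
    "SegmentationConfig",
    "VoiPair",
    "NoLesionError",
    "nonischemic_adc_stats",
    "segment_ischemic",
    "refine_clusters",
    "mirror_reference",
    "build_voi_pair",
]


class NoLesionError(Exception):
    """Raised when no voxel satisfies the ischemia criteria."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and cluster rules for ischemic VOI identification.

    ``adc_low``/``adc_high`` bound the absolute ADC window (um^2/ms); the
    literature quotes ranges 0.2-0.4 and 0.55-0.6, and the defaults take the
    midpoint of the lower range and the stricter edge of the upper one.
    ``secondary_cluster_fraction`` keeps any extra connected component at
    least that fraction of the largest one, to admit multifocal lesions.
    """

    adc_low: float = 0.30  # um^2/ms
    adc_high: float = 0.55  # um^2/ms
    t2_low: float = 30.0  # ms
    t2_high: float = 200.0  # ms
    hwhm_rule_enabled: bool = True
    cluster_connectivity: int = 26  # {6, 18, 26}
    secondary_cluster_fraction: float = 0.5
    hwhm_max_samples: int = 10000  # KDE subsample cap, deterministic stride

    def __post_init__(self) -> None:
        if not self.adc_low < self.adc_high:
            raise ValueError("adc_low must be < adc_high")
        if not self.t2_low < self.t2_high:
            raise ValueError("t2_low must be < t2_high")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0.0 <= self.secondary_cluster_fraction <= 1.0:
            raise ValueError("secondary_cluster_fraction must be in [0, 1]")

    @property
    def connectivity_structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.cluster_connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class VoiPair:
    """Ischemic VOI and its mirrored nonischemic reference."""

    ischemic: np.ndarray  # bool
    reference: np.ndarray  # bool
    nonischemic_median: float  # um^2/ms
    nonischemic_hwhm: float  # um^2/ms
    lesion_volume_ml: float

    def __post_init__(self) -> None:
        if self.ischemic.shape != self.reference.shape:
            raise ValueError("masks must share one grid")
        if not self.ischemic.any() or not self.reference.any():
            raise ValueError("both masks must be nonempty")
        if (self.ischemic & self.reference).any():
            raise ValueError("ischemic and reference masks must be disjoint")


def _kde_hwhm(values: np.ndarray, max_samples: int) -> float:
    """HWHM of a Silverman-bandwidth KDE of the values.

    Degenerate (near-constant) input falls back to half the width of one
    histogram bin over the data range, which is essentially zero.
    """
    values = np.asarray(values, dtype=float)
    span = np.ptp(values)
    if span < 1e-12 or np.std(values) < 1e-12:
        nbins = 64
        return max(span / nbins / 2.0, 1e-9)
    if values.size > max_samples:
        stride = int(np.ceil(values.size / max_samples))
        values = values[::stride]
    kde = gaussian_kde(values, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, 1024)
    dens = kde(grid)
    peak = np.argmax(dens)
    half = dens[peak] / 2.0

    def _cross(idx_range, reverse):
        # linear interpolation of the half-maximum crossing nearest the peak
        seq = idx_range[::-1] if reverse else idx_range
        if len(seq) == 0:
            return grid[peak]
        prev = peak
        for i in seq:
            if dens[i] < half:
                x0, x1 = grid[i], grid[prev]
                y0, y1 = dens[i], dens[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        return grid[seq[-1]]

    left = _cross(np.arange(0, peak), reverse=True)
    right = _cross(np.arange(peak + 1, len(grid)), reverse=False)
    return (right - left) / 2.0


def nonischemic_adc_stats(adc: np.ndarray, brain_mask: np.ndarray,
                          candidate_lesion: np.ndarray | None = None,
                          max_samples: int = 10000) -> tuple[float, float]:
    """Median and HWHM of the nonischemic ADC distribution.

    Nonischemic tissue is the brain minus the candidate lesion; the HWHM is
    half the full width at half maximum of a kernel-smoothed histogram of
    those ADC values.
    """
    nonisch = brain_mask.astype(bool).copy()
    if candidate_lesion is not None:
        nonisch &= ~candidate_lesion.astype(bool)
    if not nonisch.any():
        raise ValueError("empty nonischemic set")
    values = np.asarray(adc)[nonisch]
    return float(np.median(values)), float(_kde_hwhm(values, max_samples))


def segment_ischemic(adc: np.ndarray, t2: np.ndarray, brain_mask: np.ndarray,
                     cfg: SegmentationConfig | None = None,
                     valid: np.ndarray | None = None) -> np.ndarray:
    """Candidate ischemic mask from the ADC and T2 maps.

    A voxel is ischemic iff adc_low < ADC < adc_high, ADC < (nonischemic
    median - HWHM), and t2_low < T2 < t2_high.  Nonischemic statistics come
    from one bootstrap pass (see module docstring).

    Raises
    ------
    NoLesionError
        If no voxel passes — the no-evident-lesion outcome.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    adc = np.asarray(adc)
    t2 = np.asarray(t2)
    brain = np.asarray(brain_mask, dtype=bool)
    if not adc.shape == t2.shape == brain.shape:
        raise ValueError("maps and brain mask must share one grid")
    if valid is not None:
        brain = brain & np.asarray(valid, dtype=bool)
    window = (adc > cfg.adc_low) & (adc < cfg.adc_high)
    mask = window & brain
    if cfg.hwhm_rule_enabled:
        median, hwhm = nonischemic_adc_stats(
            adc, brain, candidate_lesion=mask, max_samples=cfg.hwhm_max_samples)
        mask &= adc < (median - hwhm)
    mask &= (t2 > cfg.t2_low) & (t2 < cfg.t2_high)
    if not mask.any():
        raise NoLesionError("no voxel satisfies the ischemia criteria")
    return mask


def refine_clusters(mask: np.ndarray, cfg: SegmentationConfig | None = None,
                    voxel_volume_ml: float = 1e-3) -> tuple[np.ndarray, float]:
    """Keep the principal connected component(s) of a candidate mask.

    Components are found at the configured connectivity; the largest is kept
    along with any component whose volume is at least
    ``secondary_cluster_fraction`` of it (multifocal lesions).  Returns the
    refined mask and the lesion volume in mL.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels, n = ndimage.label(mask, structure=cfg.connectivity_structure)
    sizes = np.bincount(labels.ravel())[1:]
    largest = sizes.max()
    keep = np.flatnonzero(sizes >= cfg.secondary_cluster_fraction * largest) + 1
    refined = np.isin(labels, keep)
    volume_ml = float(refined.sum()) * voxel_volume_ml
    return refined, volume_ml


def mirror_reference(voi: np.ndarray, t2: np.ndarray,
                     cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Reflect the ischemic VOI about the mid-sagittal plane.

    The reflection acts within each axial slice (axis 0 index i maps to
    nx - 1 - i), after which voxels violating the T2 limits are removed as
    an automatic stand-in for manual CSF editing.

    Raises
    ------
    ValueError
        If the VOI touches or crosses the midline (the bilateral-lesion
        exclusion), or the T2 filter empties the reference.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    voi = np.asarray(voi, dtype=bool)
    t2 = np.asarray(t2)
    if voi.shape != t2.shape:
        raise ValueError("VOI and T2 map must share one grid")
    if not voi.any():
        raise ValueError("VOI is empty")
    nx = voi.shape[0]
    midline = (nx - 1) / 2.0
    xs = np.flatnonzero(voi.any(axis=(1, 2)))
    if xs.min() < midline < xs.max() or np.any(xs == midline):
        raise ValueError("VOI touches the midline; bilateral lesions are excluded")
    reference = voi[::-1, :, :].copy()
    reference &= (t2 > cfg.t2_low) & (t2 < cfg.t2_high)
    if not reference.any():
        raise ValueError("T2 limits removed every reference voxel")
    return reference


def build_voi_pair(adc: np.ndarray, t2: np.ndarray, brain_mask: np.ndarray,
                   cfg: SegmentationConfig | None = None,
                   voxel_volume_ml: float = 1e-3,
                   valid: np.ndarray | None = None) -> VoiPair:
    """Full VOI pipeline: segment, refine clusters, mirror the reference."""
    if cfg is None:
        cfg = SegmentationConfig()
    candidate = segment_ischemic(adc, t2, brain_mask, cfg, valid=valid)
    ischemic, volume_ml = refine_clusters(candidate, cfg, voxel_volume_ml)
    reference = mirror_reference(ischemic, t2, cfg)
    median, hwhm = nonischemic_adc_stats(
        adc, brain_mask, candidate_lesion=ischemic,
        max_samples=cfg.hwhm_max_samples)
    return VoiPair(ischemic=ischemic, reference=reference,
                   nonischemic_median=median, nonischemic_hwhm=hwhm,
                   lesion_volume_ml=volume_ml)
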