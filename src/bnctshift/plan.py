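"""Prescription normalization, DVHs and ROI dose metrics.

The prescription fixes the beam-on time from the unperturbed plan: the
time is chosen so that the dose covering the prescribed fraction of the
tumor volume (D_80% by default) equals the prescribed dose, and that same
time is reused for every perturbed case.  Because the Gy-Eq grid is linear
in beam time, the baseline coverage dose is met exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .dose import GyEqGrid, accumulate
from .phantom import ROISet

__all__ = ["Prescription", "DVH", "RoiMetrics", "dvh", "d_percent",
           "normalize_to_prescription", "roi_metrics", "ROI_REPORT_KEYS"]

# Report-table abbreviations for the organ set.
ROI_REPORT_KEYS = {
    "tumor": "tumor",
    "normal_brain": "NB",
    "circle_of_willis": "CW",
    "optic_nerve_L": "L-ON",
    "optic_nerve_R": "R-ON",
    "lens_L": "L-lens",
    "lens_R": "R-lens",
    "eye_L": "L-eye",
    "eye_R": "R-eye",
    "brainstem": "BS",
}


@dataclass(frozen=True)
class Prescription:
    dose: float = 20.0  # Gy-Eq
    coverage: float = 80.0  # % of tumor volume

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("prescription dose must be positive")
        if not (0 < self.coverage <= 100):
            raise ValueError("coverage must lie in (0, 100] %")


@dataclass
class DVH:
    """Cumulative dose-volume histogram.

    ``edges`` are dose levels (Gy-Eq) and ``fraction`` the percentage of
    ROI volume receiving at least that dose; ``fraction[0]`` is 100.
    """

    edges: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.fraction):
            raise ValueError("edges and fraction must have equal length")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("DVH volume fraction must be non-increasing")


@dataclass
class RoiMetrics:
    """Per-ROI D_mean, D_max and coverage dose (Gy-Eq); ``None`` marks an
    absent (empty) ROI, never zero."""

    d_mean: Dict[str, Optional[float]]
    d_max: Dict[str, Optional[float]]
    d_q: Dict[str, Optional[float]]
    q: float = 80.0


def dvh(dose: GyEqGrid, mask: np.ndarray, bins: int = 512) -> DVH:
    """Cumulative DVH over the masked voxels with uniform bins from zero
    to the masked maximum."""
    values = dose.values[mask]
    if values.size == 0:
        raise ValueError("cannot build a DVH over an empty mask")
    top = float(values.max())
    if top <= 0:
        edges = np.linspace(0.0, 1.0, bins + 1)
    else:
        edges = np.linspace(0.0, top, bins + 1)
    ordered = np.sort(values)
    # share of voxels with dose >= edge; searchsorted('left') counts < edge
    frac = 100.0 * (values.size - np.searchsorted(ordered, edges, side="left")
                    ) / values.size
    return DVH(edges, frac)


def d_percent(curve: DVH, q: float) -> float:
    """Smallest dose with at least ``q`` % volume coverage, linearly
    interpolated between bracketing DVH samples."""
    if not (0 < q <= 100):
        raise ValueError("q must lie in (0, 100] %")
    frac, edges = curve.fraction, curve.edges
    below = np.nonzero(frac < q)[0]
    if below.size == 0:
        return float(edges[-1])
    j = below[0]
    if j == 0:
        return float(edges[0])
    f0, f1 = frac[j - 1], frac[j]
    if f0 == f1:  # flat segment, no crossing inside
        return float(edges[j - 1])
    w = (f0 - q) / (f0 - f1)
    return float(edges[j - 1] + w * (edges[j] - edges[j - 1]))


def normalize_to_prescription(rate: GyEqGrid, tumor_mask: np.ndarray,
                              p: Prescription = Prescription()) -> float:
    """Beam-on time (min) putting the tumor coverage dose on prescription."""
    if not rate.is_rate:
        raise ValueError("normalization requires a rate grid")
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    if rate.values[tumor_mask].max() <= 0:
        raise ValueError("tumor receives no dose: beam misses the tumor")
    dq_rate = d_percent(dvh(rate, tumor_mask), p.coverage)
    if dq_rate <= 0:
        raise ValueError("tumor coverage dose rate is zero: beam misses the tumor")
    return p.dose / dq_rate


def roi_metrics(dose: GyEqGrid, roiset: ROISet, q: float = 80.0) -> RoiMetrics:
    """D_mean, D_max and D_q for every ROI in the set."""
    d_mean: Dict[str, Optional[float]] = {}
    d_max: Dict[str, Optional[float]] = {}
    d_q: Dict[str, Optional[float]] = {}
    for name, mask in roiset.masks.items():
        if mask.shape != dose.values.shape:
            raise ValueError(f"ROI {name!r} is misaligned with the dose grid")
        if not mask.any():
            d_mean[name] = d_max[name] = d_q[name] = None
            continue
        vals = dose.values[mask]
        d_mean[name] = float(vals.mean())
        d_max[name] = float(vals.max())
        d_q[name] = d_percent(dvh(dose, mask), q)
    return RoiMetrics(d_mean, d_max, d_q, q)
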