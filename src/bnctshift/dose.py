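"""Biological weighting of physical dose components into Gy-Eq.

The four-channel weighted sum uses dose-rate scaling factors (DRSF) that
align each computed channel with measurement, RBE factors for the high-LET
(thermal nitrogen-capture plus fast neutron) and photon channels, and
compound biological effectiveness (CBE) factors for the boron channel,
tissue-dependent through the tumor mask and the tumor/normal boron
concentration ratio (T/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .beam import DoseComponents
from .phantom import ROISet

__all__ = ["WeightingConfig", "GyEqGrid", "weight_components", "accumulate"]


def _default_drsf() -> Dict[str, float]:
    return {"thermal": 0.64, "fast": 1.39, "photon": 0.96, "boron": 0.65}


@dataclass(frozen=True)
class WeightingConfig:
    """Constants converting physical dose to photon-equivalent dose.

    ``rbe_photon`` defaults to the published 0.5 for this beam (1.0 is the
    textbook convention; override if desired).  ``boron_normal_ppm`` is the
    absolute normal-tissue boron concentration; it cancels out of every
    prescription-normalized quantity, so its default (25 ppm, a typical
    BPA infusion level) only sets the absolute dose-rate scale.
    """

    drsf: Dict[str, float] = field(default_factory=_default_drsf)
    rbe_high_let: float = 3.2
    rbe_photon: float = 0.5
    cbe_tumor: float = 3.8
    cbe_normal: float = 1.3
    tn_ratio: float = 3.5
    boron_normal_ppm: float = 25.0

    def __post_init__(self) -> None:
        for ch in ("thermal", "fast", "photon", "boron"):
            if self.drsf.get(ch, 0) <= 0:
                raise ValueError(f"DRSF for {ch!r} must be positive")
        for name in ("rbe_high_let", "rbe_photon", "cbe_tumor", "cbe_normal",
                     "boron_normal_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tn_ratio < 1:
            raise ValueError("tn_ratio must be >= 1")


@dataclass
class GyEqGrid:
    """Equivalent dose-rate (Gy-Eq/min) or accumulated dose (Gy-Eq) grid."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    kind: str = "rate"  # "rate" | "accumulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("rate", "accumulated"):
            raise ValueError("kind must be 'rate' or 'accumulated'")
        if (self.values < 0).any():
            raise ValueError("Gy-Eq values must be non-negative")

    @property
    def is_rate(self) -> bool:
        return self.kind == "rate"

    def to_csv(self, path) -> None:
        """Flat (x, y, z, value) export for inspection."""
        idx = np.argwhere(np.isfinite(self.values))
        coords = (idx + 0.5) * np.asarray(self.spacing) + np.asarray(self.origin)
        data = np.column_stack([coords, self.values[tuple(idx.T)]])
        np.savetxt(path, data, delimiter=",", header="x_cm,y_cm,z_cm,gyeq",
                   comments="")


def weight_components(components: DoseComponents, weighting: WeightingConfig,
                      roiset: Optional[ROISet] = None) -> GyEqGrid:
    """Combine the four physical channels into a Gy-Eq rate grid.

    Per voxel:
    ``GyEq = drsf_th*RBE_hl*D_th + drsf_f*RBE_hl*D_f + drsf_ph*RBE_ph*D_ph
    + drsf_B*CBE(v)*C(v)*D_B_per_ppm`` with tumor voxels taking
    ``CBE = cbe_tumor`` and ``C = tn_ratio * boron_normal_ppm``; every
    voxel outside the tumor mask (including unmasked ones) is treated as
    normal tissue.
    """
    w = weighting
    if roiset is not None and "tumor" in roiset:
        tumor = roiset["tumor"]
        if tumor.shape != components.shape:
            raise ValueError("tumor mask and dose grids are misaligned")
    else:
        tumor = np.zeros(components.shape, dtype=bool)

    boron_factor = np.where(
        tumor,
        w.cbe_tumor * w.tn_ratio * w.boron_normal_ppm,
        w.cbe_normal * w.boron_normal_ppm,
    )
    values = (
        w.drsf["thermal"] * w.rbe_high_let * components.thermal
        + w.drsf["fast"] * w.rbe_high_let * components.fast
        + w.drsf["photon"] * w.rbe_photon * components.photon
        + w.drsf["boron"] * boron_factor * components.boron_per_ppm
    )
    return GyEqGrid(values, components.spacing, components.origin, kind="rate")


def accumulate(rate: GyEqGrid, beam_time: float) -> GyEqGrid:
    """Integrate a Gy-Eq rate grid over ``beam_time`` minutes."""
    if not rate.is_rate:
        raise ValueError("grid is already accumulated")
    if beam_time < 0:
        raise ValueError("beam time must be non-negative")
    return GyEqGrid(rate.values * beam_time, rate.spacing, rate.origin,
                    kind="accumulated")
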