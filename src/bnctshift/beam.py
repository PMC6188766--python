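"""Parametric epithermal-beam dose-rate engine.

This module replaces full Monte Carlo neutron/photon transport with a
separable analytic kernel: each physical dose channel at a voxel is the
product of an exit amplitude, a depth curve evaluated on the tissue path
length along the beam, an off-axis profile, and an air-gap divergence
factor.  The kernel is calibrated against the characteristics of the THOR
epithermal beam (aperture 14 cm, current-to-flux ratio 0.8, advantage
depth 8.5 cm at T/N 3.5) rather than derived from transport physics, so
absolute dose-rate values carry no metrological meaning; prescription
normalization and relative (percent-change) quantities are the supported
outputs.

Channels follow the standard four-component BNCT decomposition: thermal
neutron (including nitrogen capture), fast neutron, photon, and the boron
capture channel stored per unit ppm of tissue boron concentration.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, asdict, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .phantom import AIR_LABEL, VoxelPhantom, build_cylinder_phantom, TumorSpec

__all__ = [
    "BeamConfig",
    "KernelParams",
    "DoseComponents",
    "CalibrationTargets",
    "CalibrationReport",
    "CHANNELS",
    "depth_curve",
    "off_axis_profile",
    "air_gap_attenuation",
    "compute_dose_components",
    "advantage_depth",
    "calibrate_engine",
]

CHANNELS = ("thermal", "fast", "photon", "boron")


@dataclass(frozen=True)
class BeamConfig:
    """Epithermal beam at the aperture exit (THOR-like defaults)."""

    aperture_diameter: float = 14.0  # cm
    reactor_power: float = 1.2  # MW
    epithermal_flux_at_exit: float = 1.28e9  # n cm^-2 s^-1
    current_to_flux_ratio: float = 0.8
    beam_axis_position: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0:
            raise ValueError("aperture diameter must be positive")
        if not (0 < self.current_to_flux_ratio <= 1):
            raise ValueError("current-to-flux ratio must lie in (0, 1]")
        if self.epithermal_flux_at_exit <= 0:
            raise ValueError("exit flux must be positive")


@dataclass(frozen=True)
class KernelParams:
    """Depth-curve and lateral-profile parameters of the analytic kernel.

    Lengths in cm, amplitudes in Gy/min at the reference reactor power
    (boron amplitude in Gy/min per ppm of :sup:`10`\\ B).  The thermal and
    boron channels share the buildup-difference shape
    ``A * (exp(-d/lambda1) - exp(-d/lambda2))`` with ``lambda1 > lambda2``
    so that the curve vanishes at the surface and peaks below it.
    """

    thermal_amplitude: float = 0.55
    thermal_lambda1: float = 5.0
    thermal_lambda2: float = 1.2
    fast_amplitude: float = 0.18
    fast_attenuation: float = 1.6
    photon_amplitude: float = 0.35
    photon_attenuation: float = 6.0
    photon_buildup_fraction: float = 0.5
    photon_buildup_length: float = 1.0
    boron_amplitude_per_ppm: float = 0.022
    penumbra_width0: float = 0.6
    divergence_coeff: float = 0.15
    current_to_flux_ratio: float = 0.8
    flatness_radius0: float = 3.2
    flatness_growth: float = 1.0
    edge_radius: float = 7.0
    edge_radius_shrink: float = 0.38
    edge_radius_min: float = 2.0
    air_gap_z0: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "thermal_lambda1", "thermal_lambda2", "fast_attenuation",
            "photon_attenuation", "photon_buildup_length", "penumbra_width0",
            "flatness_radius0", "edge_radius", "air_gap_z0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thermal_lambda1 <= self.thermal_lambda2:
            raise ValueError("thermal_lambda1 must exceed thermal_lambda2 "
                             "(single interior maximum)")

    @property
    def penumbra_growth(self) -> float:
        """Penumbra widening per cm of depth+gap; forward-peaked beams
        (current-to-flux ratio near 1) diverge less."""
        return self.divergence_coeff * (1.0 - self.current_to_flux_ratio)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def for_beam(cls, beam: BeamConfig, **overrides) -> "KernelParams":
        return cls(current_to_flux_ratio=beam.current_to_flux_ratio,
                   edge_radius=beam.aperture_diameter / 2.0, **overrides)


@dataclass
class DoseComponents:
    """Per-voxel physical dose-rate grids (Gy/min at reference power).

    ``boron_per_ppm`` stores the boron-capture channel per ppm so that
    tissue-specific concentrations are applied at weighting time.
    """

    thermal: np.ndarray
    fast: np.ndarray
    photon: np.ndarray
    boron_per_ppm: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {g.shape for g in (self.thermal, self.fast, self.photon,
                                    self.boron_per_ppm)}
        if len(shapes) != 1:
            raise ValueError("dose component grids must share dimensions")
        for name in ("thermal", "fast", "photon", "boron_per_ppm"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative dose rate in {name} channel")

    @property
    def shape(self):
        return self.thermal.shape


def depth_curve(component: str, depth, params: KernelParams):
    """Depth dependence (Gy/min) of one channel at tissue depth ``depth``.

    Accepts scalars or arrays; raises on negative depth.
    """
    d = np.asarray(depth, dtype=float)
    if (d < 0).any():
        raise ValueError("depth must be non-negative")
    if component in ("thermal", "boron"):
        amp = (params.thermal_amplitude if component == "thermal"
               else params.boron_amplitude_per_ppm)
        val = amp * (np.exp(-d / params.thermal_lambda1)
                     - np.exp(-d / params.thermal_lambda2))
    elif component == "fast":
        val = params.fast_amplitude * np.exp(-d / params.fast_attenuation)
    elif component == "photon":
        val = (params.photon_amplitude
               * (1.0 - params.photon_buildup_fraction
                  * np.exp(-d / params.photon_buildup_length))
               * np.exp(-d / params.photon_attenuation))
    else:
        raise ValueError(f"unknown channel {component!r}")
    return val if val.ndim else float(val)


def thermal_peak_depth(params: KernelParams) -> float:
    """Closed-form argmax of the buildup-difference depth curve."""
    l1, l2 = params.thermal_lambda1, params.thermal_lambda2
    return l1 * l2 / (l1 - l2) * math.log(l1 / l2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def off_axis_profile(radius, depth, air_gap, beam: BeamConfig,
                     params: KernelParams):
    """Lateral dose profile, normalized to 1 on the beam axis.

    Two factors model the measured behaviour of collimated epithermal
    fields: a centre-peaked fluence component whose width grows with depth
    (in-phantom scatter flattens the central region at depth) and a
    sigmoid field edge near the aperture radius whose effective radius
    pulls inward and whose penumbra widens with depth and air gap.  The
    combination makes deep profiles flatter over the central few cm yet
    steeper across the field shoulder, which is what drives the greater
    lateral-shift vulnerability of deep targets.
    """
    r = np.asarray(radius, dtype=float)
    d = np.asarray(depth, dtype=float)
    g = np.asarray(air_gap, dtype=float)
    if (r < 0).any() or (d < 0).any() or (g < 0).any():
        raise ValueError("radius, depth and air_gap must be non-negative")
    rho = params.flatness_radius0 + params.flatness_growth * d
    peak = np.exp(-(r**2) / (2.0 * rho**2))
    r_eff = np.maximum(params.edge_radius - params.edge_radius_shrink * d,
                       params.edge_radius_min)
    w = params.penumbra_width0 + params.penumbra_growth * (d + g)
    edge = _sigmoid((r_eff - r) / w) / _sigmoid(r_eff / w)
    out = peak * np.minimum(edge, 1.0)
    return out if out.ndim else float(out)


def air_gap_attenuation(gap, beam: BeamConfig, params: KernelParams):
    """Inverse-square-like flux loss across an air gap; 1 at zero gap."""
    g = np.asarray(gap, dtype=float)
    if (g < 0).any():
        raise ValueError("air gap must be non-negative")
    out = 1.0 / (1.0 + g / params.air_gap_z0) ** 2
    return out if out.ndim else float(out)


def compute_dose_components(phantom: VoxelPhantom, beam: BeamConfig,
                            params: KernelParams) -> DoseComponents:
    """Evaluate all four physical channels on a phantom grid.

    Depth is the tissue path length accumulated along +y from the entry
    surface of each (x, z) ray; air contributes no depth but widens the
    penumbra and engages the divergence factor through the per-ray air gap
    between the aperture plane and the first tissue voxel.  Air voxels
    receive zero dose.
    """
    nx, ny, nz = phantom.shape
    dy = phantom.spacing[1]
    tissue = phantom.tissue_mask()

    bx, by, bz = beam.beam_axis_position
    x = phantom.voxel_centers(0)
    z = phantom.voxel_centers(2)
    r = np.sqrt((x[:, None] - bx) ** 2 + (z[None, :] - bz) ** 2)  # (nx, nz)

    zero = {c: np.zeros((nx, ny, nz)) for c in CHANNELS}
    if not tissue.any():
        warnings.warn("phantom contains no tissue; returning all-zero dose")
        return DoseComponents(zero["thermal"], zero["fast"], zero["photon"],
                              zero["boron"], phantom.spacing, phantom.origin)
    in_field = r <= beam.aperture_diameter / 2.0
    if not (tissue.any(axis=1) & in_field).any():
        warnings.warn("beam aperture misses the phantom; returning all-zero dose")
        return DoseComponents(zero["thermal"], zero["fast"], zero["photon"],
                              zero["boron"], phantom.spacing, phantom.origin)

    # Tissue path length to each voxel centre along +y.
    cum = np.cumsum(tissue, axis=1)
    depth = (cum - 0.5) * dy  # valid where tissue
    depth = np.where(tissue, depth, 0.0)

    # Air gap per ray: aperture plane to the front face of the first
    # tissue voxel (0 where the ray has no tissue; dose is zero there).
    has_tissue = tissue.any(axis=1)
    first = np.argmax(tissue, axis=1)
    y_entry = phantom.origin[1] + first * dy
    gap = np.where(has_tissue, np.maximum(y_entry - by, 0.0), 0.0)

    r3 = r[:, None, :]
    gap3 = gap[:, None, :]
    profile = off_axis_profile(np.broadcast_to(r3, depth.shape), depth,
                               np.broadcast_to(gap3, depth.shape), beam, params)
    gapfac = air_gap_attenuation(gap, beam, params)[:, None, :]
    lateral = np.where(tissue, profile * gapfac, 0.0)

    grids = {}
    for c in CHANNELS:
        grids[c] = np.where(tissue, depth_curve(c, depth, params) * lateral, 0.0)
    return DoseComponents(grids["thermal"], grids["fast"], grids["photon"],
                          grids["boron"], phantom.spacing, phantom.origin)


# ---------------------------------------------------------------------------
# Advantage depth and calibration


def _axis_gyeq_rates(params: KernelParams, weighting, depths: np.ndarray,
                     tn_ratio: Optional[float] = None):
    """On-axis tumor and normal-tissue Gy-Eq/min rates vs depth."""
    tn = weighting.tn_ratio if tn_ratio is None else tn_ratio
    shared = (
        weighting.drsf["thermal"] * weighting.rbe_high_let
        * depth_curve("thermal", depths, params)
        + weighting.drsf["fast"] * weighting.rbe_high_let
        * depth_curve("fast", depths, params)
        + weighting.drsf["photon"] * weighting.rbe_photon
        * depth_curve("photon", depths, params)
    )
    boron = weighting.drsf["boron"] * depth_curve("boron", depths, params)
    tumor = shared + boron * weighting.cbe_tumor * tn * weighting.boron_normal_ppm
    normal = shared + boron * weighting.cbe_normal * weighting.boron_normal_ppm
    return tumor, normal


def advantage_depth(params: KernelParams, weighting,
                    tn_ratio: Optional[float] = None,
                    d_max: float = 25.0) -> float:
    """Depth at which the on-axis tumor Gy-Eq rate falls to the maximum
    normal-tissue Gy-Eq rate (bisection on a 0.01 cm grid refined by
    Brent's method)."""
    depths = np.arange(0.0, d_max + 1e-9, 0.01)
    tumor, normal = _axis_gyeq_rates(params, weighting, depths, tn_ratio)
    i_max = int(np.argmax(normal))
    peak = float(normal[i_max])

    def f(d):
        t, _ = _axis_gyeq_rates(params, weighting, np.asarray([d]), tn_ratio)
        return float(t[0]) - peak

    if f(depths[i_max]) <= 0:
        return float(depths[i_max])
    below = np.nonzero(tumor[i_max:] <= peak)[0]
    if below.size == 0:
        raise RuntimeError(
            "tumor dose-rate curve never falls to the normal-tissue maximum; "
            "engine miscalibrated")
    j = i_max + below[0]
    return float(brentq(f, depths[j - 1], depths[j], xtol=1e-6))


@dataclass(frozen=True)
class CalibrationTargets:
    """Hard and soft targets for the kernel calibration.

    The advantage depth is a hard constraint; the loss envelopes are soft
    descriptors of the beam's positioning tolerance (fraction of the deep
    tumor's mean dose lost at a 3 cm air gap, and at a 1 cm lateral shift).
    """

    advantage_depth: float = 8.5  # cm
    advantage_depth_tol: float = 0.2  # cm
    gap3_loss_range: Tuple[float, float] = (0.10, 0.17)
    lateral1_loss_max: float = 0.03


@dataclass
class CalibrationReport:
    params: KernelParams
    achieved_ad: float
    soft_checks: Dict[str, dict]
    calibration_id: str

    def to_dict(self) -> dict:
        return {
            "calibration_id": self.calibration_id,
            "achieved_advantage_depth_cm": self.achieved_ad,
            "params": asdict(self.params),
            "soft_checks": self.soft_checks,
        }


def _deep_tumor_loss(params: KernelParams, beam: BeamConfig, weighting,
                     shift_x: float = 0.0, shift_y: float = 0.0) -> float:
    """Fractional mean-tumor-dose loss for the 6.5 cm cylinder tumor under
    a rigid translation, used for the soft calibration checks."""
    from .dose import weight_components
    from .geometry import RigidTransform, apply_transform

    phantom, rois = build_cylinder_phantom(tumor=TumorSpec(depth=6.5))
    base = weight_components(compute_dose_components(phantom, beam, params),
                             weighting, rois)
    d0 = float(base.values[rois["tumor"]].mean())
    t = RigidTransform(np.eye(3), np.array([shift_x, shift_y, 0.0]))
    ph2, rois2 = apply_transform(phantom, rois, t)
    shifted = weight_components(compute_dose_components(ph2, beam, params),
                                weighting, rois2)
    d1 = float(shifted.values[rois2["tumor"]].mean())
    return 1.0 - d1 / d0


def calibrate_engine(beam: BeamConfig, weighting,
                     targets: CalibrationTargets = CalibrationTargets(),
                     check_soft: bool = True) -> CalibrationReport:
    """Deterministic calibration of the kernel against the beam targets.

    The thermal/boron decay length ``lambda1`` is the one degree of freedom
    solved (by Brent's method) so the advantage depth matches the hard
    target; all other parameters keep their beam-derived defaults.  Soft
    envelope checks are evaluated on the default cylinder phantom and
    recorded in the report; a hard-target failure raises.
    """
    base = KernelParams.for_beam(beam)

    def ad_err(lambda1: float) -> float:
        p = replace(base, thermal_lambda1=lambda1)
        try:
            return advantage_depth(p, weighting) - targets.advantage_depth
        except RuntimeError:
            return float("inf")

    lo, hi = 2.0, 12.0
    flo, fhi = ad_err(lo), ad_err(hi)
    if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
        raise RuntimeError(
            f"advantage-depth target {targets.advantage_depth} cm infeasible "
            f"for lambda1 in [{lo}, {hi}] (errors {flo:.3g}, {fhi:.3g})")
    lambda1 = brentq(ad_err, lo, hi, xtol=1e-6)
    params = replace(base, thermal_lambda1=float(lambda1))
    achieved = advantage_depth(params, weighting)
    if abs(achieved - targets.advantage_depth) > targets.advantage_depth_tol:
        raise RuntimeError(
            f"calibrated advantage depth {achieved:.3f} cm outside "
            f"{targets.advantage_depth} +/- {targets.advantage_depth_tol} cm")

    soft: Dict[str, dict] = {}
    if check_soft:
        gap_loss = _deep_tumor_loss(params, beam, weighting, shift_y=3.0)
        lat_loss = _deep_tumor_loss(params, beam, weighting, shift_x=1.0)
        lo_g, hi_g = targets.gap3_loss_range
        soft["outward_3cm_deep_loss"] = {
            "value": gap_loss, "target": list(targets.gap3_loss_range),
            "pass": bool(lo_g <= gap_loss <= hi_g)}
        soft["lateral_1cm_deep_loss"] = {
            "value": lat_loss, "target_max": targets.lateral1_loss_max,
            "pass": bool(lat_loss <= targets.lateral1_loss_max)}
    return CalibrationReport(params, achieved, soft, params.digest())
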