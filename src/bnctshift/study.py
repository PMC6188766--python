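"""End-to-end positioning-sensitivity study.

Runs the full perturbation battery (lateral shifts in four directions,
outward shifts, rotations and tilts in both senses) at two tumor depths on
the cylinder and head phantom families, normalizes each family/depth
baseline to the prescription, reuses that beam-on time for every perturbed
case, and aggregates directional results into the report table set
(dose tables, rotation/tilt table, percent-change table, normal-tissue
table, DVH and off-axis-profile exports).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .beam import (BeamConfig, CalibrationReport, KernelParams,
                   calibrate_engine, compute_dose_components,
                   off_axis_profile)
from .dose import WeightingConfig, accumulate, weight_components
from .geometry import ShiftSpec, apply_transform, transform_from_spec
from .phantom import ROISet, TumorSpec, VoxelPhantom, build_cylinder_phantom, \
    build_head_phantom
from .plan import DVH, Prescription, ROI_REPORT_KEYS, dvh, \
    normalize_to_prescription, roi_metrics, RoiMetrics

__all__ = ["StudyConfig", "CaseResult", "AggregateRow", "StudyReport",
           "run_study", "aggregate_directional", "percent_change",
           "t_test_vs_baseline", "export_report", "default_battery"]

LATERAL_KINDS = ("left", "right", "superior", "inferior")


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions: phantom families, tumor depths, perturbation
    battery, beam, weighting and prescription."""

    families: Tuple[str, ...] = ("cylinder", "head")
    depths: Tuple[float, ...] = (6.5, 2.5)
    shift_magnitudes: Tuple[float, ...] = (1.0, 2.0, 3.0)
    angles: Tuple[float, ...] = (5.0, 10.0, 15.0)
    include_angular: bool = True
    spacing: float = 0.5  # cm, isotropic study grid
    beam: BeamConfig = BeamConfig()
    weighting: WeightingConfig = WeightingConfig()
    prescription: Prescription = Prescription()
    seed: int = 0

    def battery(self) -> List[ShiftSpec]:
        return default_battery(self)


def default_battery(config: StudyConfig) -> List[ShiftSpec]:
    specs = [ShiftSpec("none", 0.0)]
    for m in config.shift_magnitudes:
        for kind in LATERAL_KINDS:
            specs.append(ShiftSpec(kind, m))
        specs.append(ShiftSpec("outward", m))
    if config.include_angular:
        for a in config.angles:
            for kind in ("rotation", "tilt"):
                specs.append(ShiftSpec(kind, a))
                specs.append(ShiftSpec(kind, -a))
    return specs


@dataclass
class CaseResult:
    family: str
    depth: float
    shift: ShiftSpec
    metrics: RoiMetrics
    tumor_dvh: DVH
    beam_time: float


@dataclass
class AggregateRow:
    """Mean +/- sample SD of one metric over a direction family, with a
    two-sided one-sample p-value against the deterministic baseline."""

    label: str
    magnitude: float
    mean: float
    sd: float
    n: int
    p_value: Optional[float]
    p_defined: bool


@dataclass
class StudyReport:
    config: StudyConfig
    calibration: CalibrationReport
    cases: List[CaseResult]
    tables: Dict[str, pd.DataFrame]
    dvhs: Dict[str, pd.DataFrame]
    profiles: pd.DataFrame
    beam_times: Dict[Tuple[str, float], float]


def percent_change(baseline: float, shifted: float) -> float:
    """Percent decrease from baseline, rounded to two decimals with
    half-away-from-zero rounding."""
    if baseline <= 0:
        raise ValueError("baseline dose must be positive")
    raw = 100.0 * (baseline - shifted) / baseline
    return float(Decimal(repr(raw)).quantize(Decimal("0.01"),
                                             rounding=ROUND_HALF_UP))


def t_test_vs_baseline(values: Sequence[float], baseline: float
                       ) -> Tuple[Optional[float], bool]:
    """Two-sided one-sample t-test of ``values`` against the deterministic
    baseline.  Returns ``(p, defined)``; a zero sample SD makes the test
    undefined (flagged, never reported as 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("t-test needs at least two values")
    sd = arr.std(ddof=1)
    if sd == 0:
        return None, False
    t = (arr.mean() - baseline) / (sd / math.sqrt(arr.size))
    p = 2.0 * stats.t.sf(abs(t), df=arr.size - 1)
    return float(p), True


def aggregate_directional(values: Sequence[float], baseline: float,
                          label: str = "", magnitude: float = 0.0
                          ) -> AggregateRow:
    """Mean and sample SD (n-1) over a direction family plus the p-value
    from :func:`t_test_vs_baseline`."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("directional aggregation needs at least two values")
    p, defined = t_test_vs_baseline(arr, baseline)
    return AggregateRow(label, magnitude, float(arr.mean()),
                        float(arr.std(ddof=1)), int(arr.size), p, defined)


# ---------------------------------------------------------------------------
# Pipeline


def _build(family: str, depth: float, config: StudyConfig
           ) -> Tuple[VoxelPhantom, ROISet]:
    sp = (config.spacing,) * 3
    tumor = TumorSpec(depth=depth)
    if family == "cylinder":
        return build_cylinder_phantom(spacing=sp, tumor=tumor)
    if family == "head":
        return build_head_phantom(spacing=sp, tumor=tumor)
    raise ValueError(f"unknown phantom family {family!r}")


def _case_dose(phantom: VoxelPhantom, rois: ROISet, config: StudyConfig,
               params: KernelParams):
    comps = compute_dose_components(phantom, config.beam, params)
    return weight_components(comps, config.weighting, rois)


def run_study(config: StudyConfig = StudyConfig(),
              params: Optional[KernelParams] = None,
              calibration: Optional[CalibrationReport] = None) -> StudyReport:
    """Run baseline plus the full battery for every (family, depth).

    Deterministic for a given config; the baseline case defines the
    beam-on time reused by all sibling cases.
    """
    if calibration is None:
        if params is None:
            calibration = calibrate_engine(config.beam, config.weighting,
                                           check_soft=False)
        else:
            calibration = CalibrationReport(params, float("nan"), {},
                                            params.digest())
    params = calibration.params

    cases: List[CaseResult] = []
    beam_times: Dict[Tuple[str, float], float] = {}
    dvhs: Dict[str, pd.DataFrame] = {}
    for family in config.families:
        for depth in config.depths:
            try:
                phantom, rois = _build(family, depth, config)
                rate = _case_dose(phantom, rois, config, params)
                beam_time = normalize_to_prescription(
                    rate, rois["tumor"], config.prescription)
                beam_times[(family, depth)] = beam_time
                # Isocenter convention: rotational setup errors pivot about
                # the target centroid (the planning isocenter).
                ti = np.argwhere(rois["tumor"]).mean(axis=0) + 0.5
                isocenter = tuple(
                    phantom.origin[a] + ti[a] * phantom.spacing[a]
                    for a in range(3))
                for shift in config.battery():
                    if shift.kind == "none":
                        ph, rs = phantom, rois
                    else:
                        t = transform_from_spec(shift, config.beam,
                                                pivot=isocenter)
                        ph, rs = apply_transform(phantom, rois, t)
                    dose = accumulate(_case_dose(ph, rs, config, params),
                                      beam_time)
                    metrics = roi_metrics(dose, rs,
                                          q=config.prescription.coverage)
                    curve = dvh(dose, rs["tumor"])
                    cases.append(CaseResult(family, depth, shift, metrics,
                                            curve, beam_time))
                    key = (f"{family}_T{depth}_{shift.kind}"
                           f"{abs(shift.magnitude):g}"
                           f"{'m' if shift.magnitude < 0 else ''}")
                    dvhs[key] = pd.DataFrame(
                        {"dose_gyeq": curve.edges,
                         "volume_pct": curve.fraction})
            except Exception as exc:
                raise RuntimeError(
                    f"study failed for family={family!r} depth={depth} "
                    f"({exc})") from exc

    tables = _build_tables(cases, config)
    profiles = _profile_table(config, params)
    return StudyReport(config, calibration, cases, tables, dvhs, profiles,
                       beam_times)


def _case_lookup(cases: List[CaseResult]):
    idx: Dict[Tuple[str, float, str, float], CaseResult] = {}
    for c in cases:
        idx[(c.family, c.depth, c.shift.kind, c.shift.magnitude)] = c
    return idx


def _tumor_dmetric(case: CaseResult, which: str) -> float:
    return (case.metrics.d_mean["tumor"] if which == "mean"
            else case.metrics.d_q["tumor"])


def _dose_table(cases: List[CaseResult], config: StudyConfig, family: str
                ) -> pd.DataFrame:
    """Shift dose table: one row per (depth, metric), columns baseline,
    lateral aggregates (mean/SD/p over the four directions) and outward
    shifts."""
    idx = _case_lookup(cases)
    rows = []
    for depth in config.depths:
        base = idx.get((family, depth, "none", 0.0))
        if base is None:
            continue
        for which, metric_name in (("mean", "D_mean"), ("q", "D_80%")):
            row: Dict[str, object] = {"depth_cm": depth, "metric": metric_name,
                                      "baseline": _tumor_dmetric(base, which)}
            for m in config.shift_magnitudes:
                vals = [_tumor_dmetric(idx[(family, depth, k, m)], which)
                        for k in LATERAL_KINDS]
                agg = aggregate_directional(vals, row["baseline"],
                                            label=f"LS{m:g}", magnitude=m)
                row[f"LS{m:g}_mean"] = agg.mean
                row[f"LS{m:g}_sd"] = agg.sd
                row[f"LS{m:g}_p"] = agg.p_value if agg.p_defined else float("nan")
                out = idx[(family, depth, "outward", m)]
                row[f"OS{m:g}"] = _tumor_dmetric(out, which)
            rows.append(row)
    return pd.DataFrame(rows)


def _angular_table(cases: List[CaseResult], config: StudyConfig,
                   family: str = "head") -> pd.DataFrame:
    idx = _case_lookup(cases)
    rows = []
    for depth in config.depths:
        base = idx.get((family, depth, "none", 0.0))
        if base is None:
            continue
        for which, metric_name in (("mean", "D_mean"), ("q", "D_80%")):
            row: Dict[str, object] = {"depth_cm": depth, "metric": metric_name,
                                      "baseline": _tumor_dmetric(base, which)}
            for kind, prefix in (("rotation", "R"), ("tilt", "T")):
                for a in config.angles:
                    vals = [_tumor_dmetric(idx[(family, depth, kind, s * a)],
                                           which) for s in (1, -1)]
                    agg = aggregate_directional(vals, row["baseline"],
                                                label=f"{prefix}{a:g}",
                                                magnitude=a)
                    row[f"{prefix}{a:g}_mean"] = agg.mean
                    row[f"{prefix}{a:g}_sd"] = agg.sd
                    row[f"{prefix}{a:g}_p"] = (agg.p_value if agg.p_defined
                                               else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def _percent_table(table_cyl: pd.DataFrame, table_head: pd.DataFrame,
                   config: StudyConfig) -> pd.DataFrame:
    """Percent changes in mean tumor dose, recomputable from the dose
    tables in the same report (head columns first, then cylinder)."""
    rows = []
    for m in config.shift_magnitudes:
        for shift_kind, key in (("lateral", f"LS{m:g}_mean"),
                                ("outward", f"OS{m:g}")):
            row: Dict[str, object] = {
                "shift": f"{m:g} cm {shift_kind} shift"}
            for family, table in (("head", table_head),
                                  ("cylinder", table_cyl)):
                if table.empty:
                    continue
                for depth in config.depths:
                    sel = table[(table.depth_cm == depth)
                                & (table.metric == "D_mean")]
                    if sel.empty:
                        continue
                    base = float(sel.iloc[0]["baseline"])
                    shifted = float(sel.iloc[0][key])
                    row[f"{family}_T{depth:g}"] = percent_change(base, shifted)
            rows.append(row)
    df = pd.DataFrame(rows)
    order = [c for c in ("shift", "head_T6.5", "head_T2.5",
                         "cylinder_T6.5", "cylinder_T2.5") if c in df.columns]
    other = [c for c in df.columns if c not in order]
    return df[order + other]


def _normal_tissue_table(cases: List[CaseResult], config: StudyConfig,
                         family: str = "head") -> pd.DataFrame:
    idx = _case_lookup(cases)
    rows = []
    organs = [n for n in ROI_REPORT_KEYS if n != "tumor"]
    for organ in organs:
        for stat_name in (("d_mean",) if organ != "normal_brain"
                          else ("d_mean", "d_max")):
            row: Dict[str, object] = {
                "organ": ROI_REPORT_KEYS[organ],
                "metric": {"d_mean": "D_mean", "d_max": "D_max"}[stat_name]}
            any_depth = False
            for depth in config.depths:
                base = idx.get((family, depth, "none", 0.0))
                if base is None:
                    continue
                any_depth = True
                getter = (lambda c: getattr(c.metrics, stat_name)[organ])
                row[f"baseline_T{depth:g}"] = getter(base)
                for m in config.shift_magnitudes:
                    vals = [getter(idx[(family, depth, k, m)])
                            for k in LATERAL_KINDS]
                    vals = [v for v in vals if v is not None]
                    if len(vals) >= 2:
                        agg = aggregate_directional(vals,
                                                    row[f"baseline_T{depth:g}"])
                        row[f"LS{m:g}_T{depth:g}"] = agg.mean
                        row[f"LS{m:g}_sd_T{depth:g}"] = agg.sd
                    out = idx[(family, depth, "outward", m)]
                    row[f"OS{m:g}_T{depth:g}"] = getter(out)
            if any_depth:
                rows.append(row)
    return pd.DataFrame(rows)


def _profile_table(config: StudyConfig, params: KernelParams) -> pd.DataFrame:
    radii = np.linspace(0.0, 10.0, 201)
    rows = {"radius_cm": radii}
    for depth in sorted(config.depths):
        rows[f"profile_depth_{depth:g}cm"] = off_axis_profile(
            radii, np.full_like(radii, depth), np.zeros_like(radii),
            config.beam, params)
    return pd.DataFrame(rows)


def _build_tables(cases: List[CaseResult], config: StudyConfig
                  ) -> Dict[str, pd.DataFrame]:
    tables: Dict[str, pd.DataFrame] = {}
    tables["table1"] = _dose_table(cases, config, "cylinder")
    tables["table2"] = _dose_table(cases, config, "head")
    if config.include_angular:
        tables["table3"] = _angular_table(cases, config, "head")
    tables["table4"] = _percent_table(tables["table1"], tables["table2"],
                                      config)
    tables["table5"] = _normal_tissue_table(cases, config, "head")
    return tables


# ---------------------------------------------------------------------------
# Export


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d


def config_hash(config: StudyConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def export_report(report: StudyReport, directory) -> List[Path]:
    """Write the table set, DVHs, profiles and a run manifest as CSV/text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name, table in report.tables.items():
        path = directory / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    dvh_dir = directory / "dvh"
    dvh_dir.mkdir(exist_ok=True)
    for key, df in report.dvhs.items():
        path = dvh_dir / f"{key}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    path = directory / "profiles.csv"
    report.profiles.to_csv(path, index=False)
    written.append(path)
    manifest = {
        "config_hash": config_hash(report.config),
        "seed": report.config.seed,
        "calibration_id": report.calibration.calibration_id,
        "beam_times_min": {f"{k[0]}_T{k[1]:g}": v
                           for k, v in report.beam_times.items()},
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
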