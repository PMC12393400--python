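"""Point-source NaCl gradient prediction for agar-plate chemotaxis assays.

A salt gradient is set up by pipetting small drops of concentrated NaCl onto
one marked point of an unseeded agar plate several hours before the assay.
Each drop spreads through the agar slab by two-dimensional diffusion, so at
a distance ``r`` (cm) from the application point, ``t`` seconds after the
drop was applied, it adds

    c(t, r) = 1e6 * N / (4 pi d D t) * exp(-r**2 / (4 D t))      [mM]

where ``N`` is the moles of NaCl in the drop, ``d`` the agar depth (cm) and
``D`` the diffusion coefficient (cm^2/s).  The 1e6 factor converts the areal
density ``N / (4 pi D t)`` spread over depth ``d`` from mol/cm^3 to mM.  The
plate-wide prediction superposes all drops on the uniform baseline
concentration ``Co`` of the growth medium (about 50 mM NaCl for NGM).

The kernel is the free-space (infinite plane) Green's function; no boundary
correction is applied at the plate wall.  This overestimates how fast salt
leaves the neighbourhood of the peak at long times, but over the few hours
between drop application and assay the approximation is good away from the
wall.  Lengths are cm inside this module; millimetres appear only at the
plate-coordinate I/O boundary (:func:`predict_field`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PlateModel",
    "DropEvent",
    "GradientSchedule",
    "ConcentrationField",
    "ConductivityCalibration",
    "moles_from_drop",
    "drop_contribution",
    "predict_concentration",
    "predict_field",
    "calibrate_conductivity",
    "load_gradient_config",
]

#: diffusion coefficient of concentrated NaCl in aqueous medium, cm^2/s
DEFAULT_DIFFUSION_D = 1.590e-5


@dataclass(frozen=True)
class PlateModel:
    """Geometry and physical constants of one assay plate.

    Parameters
    ----------
    radius_cm : plate radius (default 2.5 cm, i.e. a 50 mm plate).
    agar_depth_cm : depth ``d`` of the agar slab the salt diffuses through.
    baseline_Co_mM : uniform NaCl concentration of the medium before drops.
    diffusion_D_cm2_s : diffusion coefficient ``D``.
    """

    radius_cm: float = 2.5
    agar_depth_cm: float = 0.35
    baseline_Co_mM: float = 50.0
    diffusion_D_cm2_s: float = DEFAULT_DIFFUSION_D

    def __post_init__(self) -> None:
        for name in ("radius_cm", "agar_depth_cm", "baseline_Co_mM", "diffusion_D_cm2_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PlateModel.{name} must be strictly positive")


@dataclass(frozen=True)
class DropEvent:
    """One applied NaCl drop: moles added and elapsed diffusion time."""

    moles_Ni: float
    elapsed_ti_s: float

    def __post_init__(self) -> None:
        if self.moles_Ni < 0:
            raise ValueError("moles_Ni must be non-negative")
        if not self.elapsed_ti_s > 0:
            raise ValueError("elapsed_ti_s must be strictly positive (t=0 is singular)")


@dataclass(frozen=True)
class GradientSchedule:
    """Ordered drop schedule plus the geometry of the application point.

    ``peak_offset_cm`` is the distance of the salt peak from the plate
    center (drops are applied at one marked point, 12.5 mm from center in
    the standard assay).
    """

    drops: tuple[DropEvent, ...] = ()
    peak_offset_cm: float = 1.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "drops", tuple(self.drops))
        if self.peak_offset_cm < 0:
            raise ValueError("peak_offset_cm must be non-negative")

    @classmethod
    def from_drop_plan(
        cls,
        plan: Sequence[tuple[float, float, float]],
        peak_offset_cm: float = 1.25,
    ) -> "GradientSchedule":
        """Build a schedule from (volume_uL, molarity_M, hours_before_assay) rows.

        Elapsed times are measured to assay start, i.e. the field is
        evaluated at the moment data collection begins.
        """
        drops = tuple(
            DropEvent(moles_from_drop(vol_ul, molarity), hours * 3600.0)
            for vol_ul, molarity, hours in plan
        )
        return cls(drops=drops, peak_offset_cm=peak_offset_cm)


def standard_drop_schedule(peak_offset_cm: float = 1.25) -> GradientSchedule:
    """The standard three-drop 5 M NaCl schedule: 4 uL at 22 h, 4 uL at 5 h
    and 1.6 uL at 2 h before the assay (the first drop's 20-24 h window is
    represented by its midpoint)."""
    return GradientSchedule.from_drop_plan(
        [(4.0, 5.0, 22.0), (4.0, 5.0, 5.0), (1.6, 5.0, 2.0)],
        peak_offset_cm=peak_offset_cm,
    )


def moles_from_drop(volume_ul: float, molarity_M: float) -> float:
    """Moles of solute in a pipetted drop (uL * mol/L -> mol)."""
    if volume_ul < 0 or molarity_M < 0:
        raise ValueError("volume and molarity must be non-negative")
    return volume_ul * 1e-6 * molarity_M


def drop_contribution(drop: DropEvent, r_cm, plate: PlateModel):
    """Concentration (mM) one drop adds at distance ``r_cm`` from the peak.

    Vectorised over ``r_cm``.  Rejects negative distances.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_cm must be non-negative")
    d, D, t = plate.agar_depth_cm, plate.diffusion_D_cm2_s, drop.elapsed_ti_s
    amplitude = 1e6 * drop.moles_Ni / (4.0 * math.pi * d * D * t)
    out = amplitude * np.exp(-(r**2) / (4.0 * D * t))
    return float(out) if np.isscalar(r_cm) else out


def predict_concentration(schedule: GradientSchedule, plate: PlateModel, r_cm):
    """Total concentration (mM) at distance ``r_cm`` from the salt peak.

    Superposes each drop's contribution on the baseline ``Co``; an empty
    schedule returns the baseline everywhere.
    """
    r = np.asarray(r_cm, dtype=float)
    total = np.full_like(r, plate.baseline_Co_mM, dtype=float)
    for drop in schedule.drops:
        total = total + drop_contribution(drop, r, plate)
    return float(total) if np.isscalar(r_cm) else total


@dataclass(frozen=True)
class ConcentrationField:
    """Gridded concentration over the plate, in plate coordinates (mm).

    ``values_mM[i, j]`` is the concentration at ``(x_mm[i], y_mm[j])`` with
    origin at the plate center.  ``inside[i, j]`` flags nodes within the
    plate radius.  The salt peak sits at ``peak_xy_mm``.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    values_mM: np.ndarray
    inside: np.ndarray
    peak_xy_mm: tuple[float, float]
    plate_radius_mm: float
    baseline_Co_mM: float
    eval_note: str = "assay start"

    def interpolator(self):
        """Bilinear interpolator mapping (x_mm, y_mm) points to mM."""
        from scipy.interpolate import RegularGridInterpolator

        return RegularGridInterpolator(
            (self.x_mm, self.y_mm),
            self.values_mM,
            bounds_error=False,
            fill_value=self.baseline_Co_mM,
        )

    def concentration_at(self, points_mm: np.ndarray) -> np.ndarray:
        return self.interpolator()(np.atleast_2d(points_mm))


def predict_field(
    schedule: GradientSchedule,
    plate: PlateModel,
    grid_spacing_mm: float = 0.5,
) -> ConcentrationField:
    """Evaluate the gradient model on a Cartesian grid covering the plate.

    The peak is placed on the +x axis at ``schedule.peak_offset_cm`` from
    the plate center; each node's value is the point prediction at that
    node's Euclidean distance from the peak.
    """
    if not grid_spacing_mm > 0:
        raise ValueError("grid_spacing_mm must be strictly positive")
    radius_mm = plate.radius_cm * 10.0
    n = int(math.floor(radius_mm / grid_spacing_mm))
    axis = np.arange(-n, n + 1) * grid_spacing_mm
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    peak = (schedule.peak_offset_cm * 10.0, 0.0)
    r_cm = np.hypot(xx - peak[0], yy - peak[1]) / 10.0
    values = predict_concentration(schedule, plate, r_cm)
    inside = np.hypot(xx, yy) <= radius_mm
    return ConcentrationField(
        x_mm=axis,
        y_mm=axis.copy(),
        values_mM=values,
        inside=inside,
        peak_xy_mm=peak,
        plate_radius_mm=radius_mm,
        baseline_Co_mM=plate.baseline_Co_mM,
    )


@dataclass(frozen=True)
class ConductivityCalibration:
    """Two-point linear map from conductivity-meter readings to mM NaCl.

    Built from plates of known concentration (50 and 100 mM in the standard
    protocol) read at the same room temperature as the measurement.
    """

    slope: float
    intercept: float
    ref_pairs: tuple[tuple[float, float], tuple[float, float]]

    def apply(self, reading):
        return self.slope * np.asarray(reading, dtype=float) + self.intercept

    def __call__(self, reading):
        return self.apply(reading)


def calibrate_conductivity(
    ref1: tuple[float, float], ref2: tuple[float, float]
) -> ConductivityCalibration:
    """Fit the exact line through two (reading, concentration_mM) references."""
    (x1, c1), (x2, c2) = ref1, ref2
    if x1 == x2:
        raise ValueError("reference readings must be distinct")
    if c1 == c2:
        raise ValueError("reference concentrations must be distinct")
    slope = (c2 - c1) / (x2 - x1)
    intercept = c1 - slope * x1
    return ConductivityCalibration(slope=slope, intercept=intercept, ref_pairs=(ref1, ref2))


def load_gradient_config(path: str | Path) -> tuple[GradientSchedule, PlateModel]:
    """Read a YAML gradient config.

    Schema (all keys optional, defaults are the standard assay)::

        plate:
          radius_cm: 2.5
          agar_depth_cm: 0.35
          baseline_Co_mM: 50.0
          diffusion_D_cm2_s: 1.590e-5
        peak_offset_cm: 1.25
        drops:                       # volume uL, molarity M, hours before assay
          - {volume_ul: 4.0, molarity_M: 5.0, hours_before: 22.0}
          - {volume_ul: 4.0, molarity_M: 5.0, hours_before: 5.0}
          - {volume_ul: 1.6, molarity_M: 5.0, hours_before: 2.0}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    plate = PlateModel(**(raw.get("plate") or {}))
    peak = raw.get("peak_offset_cm", 1.25)
    drop_rows = raw.get("drops")
    if drop_rows is None:
        schedule = standard_drop_schedule(peak_offset_cm=peak)
    else:
        plan = [
            (row["volume_ul"], row["molarity_M"], row["hours_before"]) for row in drop_rows
        ]
        schedule = GradientSchedule.from_drop_plan(plan, peak_offset_cm=peak)
    return schedule, plate
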