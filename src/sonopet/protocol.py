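"""Treatment planning and dosimetry arithmetic for microbubble-assisted
focused-ultrasound (FUS) blood-brain-barrier opening.

The treatment protocol modeled here electronically sweeps the focus of a
128-element, 1.5 MHz therapeutic array across a small planar grid (default
5x5 positions, 0.5 mm pitch, tilted to follow the skull) while an imaging
array passively records microbubble emissions.  This module owns the
protocol-level arithmetic: grid construction, the burst schedule, skull
derating of peak negative pressure (PNP), the mechanical index (MI),
microbubble dose normalization, and the insonified-volume estimate.

Coordinate convention (used throughout the package): right-handed, x lateral
(along the imaging-array long axis), y elevational, z depth from the
therapeutic array face; all lengths in mm, continuous physical coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InfeasibleScheduleError, InvalidParameterError

__all__ = [
    "TransducerArray",
    "TreatmentPlan",
    "BurstSchedule",
    "therapeutic_array",
    "imaging_array",
    "plan_treatment_grid",
    "build_burst_schedule",
    "derate_pnp",
    "mechanical_index",
    "mb_dose_per_kg",
    "treated_volume",
]


@dataclass(frozen=True)
class TransducerArray:
    """Geometry and drive frequency of a transducer array.

    Parameters
    ----------
    element_positions
        ``(n_elements, 3)`` array of element centers in mm.
    center_frequency_mhz
        Drive (therapeutic) or nominal receive (imaging) center frequency.
    geometric_focus_mm
        The natural focus of the (curved) aperture; for a flat imaging
        array this is a nominal reference point.
    aperture_extent_mm
        Physical extent of the aperture per axis ``(x, y, z)``.
    role
        ``"therapeutic"`` or ``"imaging"``.
    """

    element_positions: np.ndarray
    center_frequency_mhz: float
    geometric_focus_mm: np.ndarray
    aperture_extent_mm: np.ndarray
    role: str = "therapeutic"

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.element_positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise InvalidParameterError("element_positions must be (n, 3) with n >= 1")
        if self.center_frequency_mhz <= 0:
            raise InvalidParameterError("center_frequency must be positive")
        if self.role not in ("therapeutic", "imaging"):
            raise InvalidParameterError(f"unknown array role {self.role!r}")
        object.__setattr__(self, "element_positions", pos)
        object.__setattr__(
            self, "geometric_focus_mm", np.asarray(self.geometric_focus_mm, dtype=float)
        )
        object.__setattr__(
            self, "aperture_extent_mm", np.asarray(self.aperture_extent_mm, dtype=float)
        )

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]


def therapeutic_array(
    n_elements: int = 128,
    aperture_mm: float = 50.0,
    focal_depth_mm: float = 55.0,
    center_frequency_mhz: float = 1.5,
) -> TransducerArray:
    """Synthetic stand-in geometry for the 128-element therapeutic array.

    The real array's element layout is proprietary; this fixture distributes
    elements deterministically (Fibonacci disc) over a spherically curved
    aperture focused on the axis at ``focal_depth_mm``.  It reproduces the
    qualitative focusing behavior (small f-number, sub-mm transverse focus,
    mm-scale axial focus) but is *not* an authoritative description of any
    physical device.
    """
    if n_elements < 1:
        raise InvalidParameterError("n_elements must be >= 1")
    i = np.arange(n_elements, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = (aperture_mm / 2.0) * np.sqrt((i + 0.5) / n_elements)
    th = golden * i
    x = r * np.cos(th)
    y = r * np.sin(th)
    # Project onto the spherical cap of radius focal_depth centered at the focus.
    z = focal_depth_mm - np.sqrt(focal_depth_mm**2 - x**2 - y**2)
    pos = np.column_stack([x, y, z])
    return TransducerArray(
        element_positions=pos,
        center_frequency_mhz=center_frequency_mhz,
        geometric_focus_mm=np.array([0.0, 0.0, focal_depth_mm]),
        aperture_extent_mm=np.array([aperture_mm, aperture_mm, z.max()]),
        role="therapeutic",
    )


def imaging_array(
    n_elements: int = 128,
    aperture_mm: float = 38.0,
    center_frequency_mhz: float = 7.8,
) -> TransducerArray:
    """Linear imaging array (L12-5-like): n elements spanning a 38 mm
    aperture along x, in the z = 0 plane at the therapeutic array center."""
    if n_elements < 1:
        raise InvalidParameterError("n_elements must be >= 1")
    pitch = aperture_mm / n_elements
    x = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
    pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return TransducerArray(
        element_positions=pos,
        center_frequency_mhz=center_frequency_mhz,
        geometric_focus_mm=np.array([0.0, 0.0, 55.0]),
        aperture_extent_mm=np.array([aperture_mm, 0.0, 0.0]),
        role="imaging",
    )


@dataclass(frozen=True)
class TreatmentPlan:
    """Ordered steered-focus positions of one treatment grid.

    Positions are stored row-major (left-to-right within a row, rows top to
    bottom); the grid is planar with centroid at ``center_mm``, optionally
    tilted out of the nominal x-y plane to follow the skull curvature.
    """

    focus_positions_mm: np.ndarray
    grid_shape: tuple[int, int]
    step_mm: float
    tilt: Rotation
    center_mm: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.focus_positions_mm.shape[0]

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the (tilted) grid plane."""
        return self.tilt.apply(np.array([0.0, 0.0, 1.0]))

    def to_config_text(self) -> str:
        """Serialize as a key-value header plus a position list."""
        buf = io.StringIO()
        buf.write(f"grid_rows = {self.grid_shape[0]}\n")
        buf.write(f"grid_cols = {self.grid_shape[1]}\n")
        buf.write(f"step_mm = {self.step_mm:g}\n")
        cx, cy, cz = self.center_mm
        buf.write(f"center_mm = {cx:g} {cy:g} {cz:g}\n")
        rv = self.tilt.as_rotvec()
        buf.write(f"tilt_rotvec_rad = {rv[0]:.9g} {rv[1]:.9g} {rv[2]:.9g}\n")
        buf.write("positions_mm =\n")
        for p in self.focus_positions_mm:
            buf.write(f"  {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        return buf.getvalue()

    def positions_csv(self) -> str:
        lines = ["x_mm,y_mm,z_mm"]
        lines += [f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}" for p in self.focus_positions_mm]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BurstSchedule:
    """Ordered (time, grid index) pairs of the FUS burst sequence.

    One sweep visits every grid point once (``n_points * burst_ms``
    milliseconds); sweeps repeat at ``grid_repetition_rate_hz`` for
    ``total_duration_s`` seconds, so each grid point receives
    ``grid_repetition_rate_hz * total_duration_s`` bursts.
    """

    burst_duration_ms: float
    grid_repetition_rate_hz: float
    total_duration_s: float
    times_s: np.ndarray = field(repr=False)
    grid_indices: np.ndarray = field(repr=False)

    @property
    def n_bursts(self) -> int:
        return self.times_s.size

    def bursts_per_point(self, n_points: int) -> int:
        return self.n_bursts // n_points if n_points else 0

    @property
    def sweep_duration_ms(self) -> float:
        n_points = int(self.grid_indices.max()) + 1 if self.n_bursts else 0
        return n_points * self.burst_duration_ms

    def to_config_text(self) -> str:
        return (
            f"burst_duration_ms = {self.burst_duration_ms:g}\n"
            f"grid_repetition_rate_hz = {self.grid_repetition_rate_hz:g}\n"
            f"total_duration_s = {self.total_duration_s:g}\n"
            f"n_bursts = {self.n_bursts}\n"
        )


def plan_treatment_grid(
    center_mm,
    rows: int = 5,
    cols: int = 5,
    step_mm: float = 0.5,
    tilt: Rotation | None = None,
) -> TreatmentPlan:
    """Plan a planar steered-focus grid centered on ``center_mm``.

    The default reproduces the study protocol: a 5x5 grid with 0.5 mm steps
    centered near the geometric focus, optionally tilted so the grid plane
    follows the skull.  Columns run along +x, rows along -y (top to bottom),
    and the centroid of the returned positions equals ``center_mm`` exactly.
    """
    if rows < 1 or cols < 1:
        raise InvalidParameterError("rows and cols must be >= 1")
    if step_mm <= 0:
        raise InvalidParameterError("step must be positive")
    if tilt is None:
        tilt = Rotation.identity()
    center = np.asarray(center_mm, dtype=float)
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    dx = (jj.ravel() - (cols - 1) / 2.0) * step_mm
    dy = ((rows - 1) / 2.0 - ii.ravel()) * step_mm
    offsets = np.column_stack([dx, dy, np.zeros_like(dx)])
    positions = center + tilt.apply(offsets)
    return TreatmentPlan(
        focus_positions_mm=positions,
        grid_shape=(rows, cols),
        step_mm=step_mm,
        tilt=tilt,
        center_mm=center,
    )


def build_burst_schedule(
    plan: TreatmentPlan,
    burst_ms: float = 1.0,
    rep_hz: float = 5.0,
    total_s: float = 120.0,
) -> BurstSchedule:
    """Build the burst schedule sweeping ``plan`` at ``rep_hz`` for ``total_s``.

    Defaults give the study protocol: 1 ms bursts, 5 Hz grid repetition for
    2 min -> 600 bursts per grid point, one 25 ms sweep per repetition for a
    25-point grid.

    Raises
    ------
    InfeasibleScheduleError
        If one full sweep (``n_points * burst_ms``) does not fit inside a
        repetition period ``1 / rep_hz``.
    """
    if burst_ms <= 0 or rep_hz <= 0:
        raise InvalidParameterError("burst_ms and rep_hz must be positive")
    if total_s < 0:
        raise InvalidParameterError("total_s must be nonnegative")
    n_points = plan.n_positions
    sweep_s = n_points * burst_ms / 1000.0
    if sweep_s > 1.0 / rep_hz:
        raise InfeasibleScheduleError(
            f"sweep of {n_points} x {burst_ms} ms = {sweep_s * 1e3:g} ms exceeds the "
            f"repetition period {1e3 / rep_hz:g} ms"
        )
    n_sweeps = int(round(rep_hz * total_s))
    sweep_starts = np.arange(n_sweeps) / rep_hz
    within = np.arange(n_points) * burst_ms / 1000.0
    times = (sweep_starts[:, None] + within[None, :]).ravel()
    indices = np.tile(np.arange(n_points), n_sweeps)
    return BurstSchedule(
        burst_duration_ms=burst_ms,
        grid_repetition_rate_hz=rep_hz,
        total_duration_s=total_s,
        times_s=times,
        grid_indices=indices,
    )


def derate_pnp(pnp_free_field_kpa: float, insertion_loss: float) -> float:
    """Derate a free-field peak negative pressure by a scalar skull
    insertion loss (fractional pressure reduction; murine skull at 1.5 MHz
    is ~0.20): returns ``pnp * (1 - loss)``."""
    if not 0.0 <= insertion_loss < 1.0:
        raise InvalidParameterError("insertion_loss must be in [0, 1)")
    if pnp_free_field_kpa < 0:
        raise InvalidParameterError("pnp must be nonnegative")
    return pnp_free_field_kpa * (1.0 - insertion_loss)


def mechanical_index(pnp_kpa: float, freq_mhz: float) -> float:
    """Mechanical index MI = PNP[MPa] / sqrt(f[MHz]).

    The standard cavitation-risk index of diagnostic ultrasound; summaries
    report it rounded to two decimals.
    """
    if freq_mhz <= 0:
        raise InvalidParameterError("frequency must be positive")
    if pnp_kpa < 0:
        raise InvalidParameterError("pnp must be nonnegative")
    return (pnp_kpa / 1000.0) / np.sqrt(freq_mhz)


def mb_dose_per_kg(n_mb: float, body_mass_g: float) -> float:
    """Microbubble dose normalized to body mass (MB/kg)."""
    if body_mass_g <= 0:
        raise InvalidParameterError("body mass must be positive")
    if n_mb < 0:
        raise InvalidParameterError("microbubble count must be nonnegative")
    return n_mb / (body_mass_g / 1000.0)


def treated_volume(extent_x_mm: float, extent_y_mm: float, extent_z_mm: float) -> float:
    """Insonified-volume estimate: product of the three grid/focal extents.

    Reported values are conventionally rounded to the nearest integer mm^3
    (e.g. 2.5 x 2.5 x 2.7 mm -> 16.875 -> 17 mm^3); the exact product is
    returned.
    """
    if extent_x_mm <= 0 or extent_y_mm <= 0 or extent_z_mm <= 0:
        raise InvalidParameterError("extents must be positive")
    return extent_x_mm * extent_y_mm * extent_z_mm
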