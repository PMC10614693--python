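"""Monochromatic steered-focus pressure-field model.

A continuous-wave Rayleigh-type point-source superposition over the
therapeutic array: each element radiates a spherical wave and its drive
phase is chosen so all contributions arrive in phase at the steered focus,

    p(r) = | sum_e  a_e * exp(i k (|r - r_e| - |r_f - r_e|)) / |r - r_e| |,

with wavenumber k = 2*pi*f/c.  The 1 ms treatment bursts contain ~1500
cycles at 1.5 MHz, so a single-frequency CW model is adequate for the two
quantities this module feeds downstream: per-position drive compensation
factors (equalizing focal pressure across the steered grid) and focal
dimensions at a dB threshold.

Element directivity and baffle factors are ignored (point sources), and the
skull enters only as the scalar insertion loss applied in
:mod:`sonopet.protocol`; attenuation of the bulk medium is available as a
simple dB/cm/MHz amplitude law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, SingularGeometryError, SteeringRangeWarning
from .protocol import TransducerArray, TreatmentPlan

__all__ = [
    "Medium",
    "EvaluationGrid",
    "PressureField",
    "CompensationTable",
    "simulate_steered_field",
    "steered_focus_amplitude",
    "compensation_factors",
    "focal_dimensions",
]

WATER_SOUND_SPEED_M_S = 1480.0
TISSUE_SOUND_SPEED_M_S = 1540.0


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium.

    speed_of_sound_m_s: 1540 m/s default (soft tissue); use 1480 for
    water-tank replication.  attenuation_db_cm_mhz: amplitude attenuation
    coefficient, 0 by default (degassed water / lossless).
    """

    speed_of_sound_m_s: float = TISSUE_SOUND_SPEED_M_S
    attenuation_db_cm_mhz: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_of_sound_m_s <= 0:
            raise InvalidParameterError("speed of sound must be positive")
        if self.attenuation_db_cm_mhz < 0:
            raise InvalidParameterError("attenuation must be nonnegative")

    def wavenumber_rad_mm(self, freq_mhz: float) -> float:
        """k = 2*pi*f/c in rad/mm."""
        return 2.0 * np.pi * freq_mhz * 1e6 / (self.speed_of_sound_m_s * 1e3)


@dataclass(frozen=True)
class EvaluationGrid:
    """Regular 3-D lattice of evaluation points (axes in mm)."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray

    @classmethod
    def around(
        cls,
        center_mm,
        half_extent_mm=(3.0, 3.0, 5.0),
        spacing_mm: float = 0.1,
    ) -> "EvaluationGrid":
        """Default box: 6 x 6 x 10 mm at 0.1 mm spacing around ``center_mm``."""
        c = np.asarray(center_mm, dtype=float)
        axes = []
        for ci, h in zip(c, half_extent_mm):
            n = int(round(2 * h / spacing_mm)) + 1
            axes.append(ci + (np.arange(n) - (n - 1) / 2.0) * spacing_mm)
        return cls(x_mm=axes[0], y_mm=axes[1], z_mm=axes[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x_mm.size, self.y_mm.size, self.z_mm.size)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        def sp(a):
            return float(a[1] - a[0]) if a.size > 1 else 0.0

        return (sp(self.x_mm), sp(self.y_mm), sp(self.z_mm))

    def points(self) -> np.ndarray:
        """All lattice points, shape (nx*ny*nz, 3), x fastest varying last."""
        X, Y, Z = np.meshgrid(self.x_mm, self.y_mm, self.z_mm, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass(frozen=True)
class PressureField:
    """Amplitude of the simulated pressure field on an evaluation lattice.

    Amplitudes are in relative field units (element drive amplitude at
    1 mm); the field is linear in the global drive amplitude.
    """

    grid: EvaluationGrid
    amplitude: np.ndarray
    frequency_mhz: float
    drive: np.ndarray
    focus_mm: np.ndarray

    def peak(self) -> tuple[float, np.ndarray]:
        """(peak amplitude, peak position mm)."""
        idx = int(np.argmax(self.amplitude))
        i, j, k = np.unravel_index(idx, self.amplitude.shape)
        pos = np.array([self.grid.x_mm[i], self.grid.y_mm[j], self.grid.z_mm[k]])
        return float(self.amplitude[i, j, k]), pos


@dataclass(frozen=True)
class CompensationTable:
    """Per-position drive scale factors relative to the geometric focus."""

    positions_mm: np.ndarray
    factors: np.ndarray
    reference_peak: float

    def to_csv(self) -> str:
        lines = ["index,x_mm,y_mm,z_mm,factor"]
        for i, (p, f) in enumerate(zip(self.positions_mm, self.factors)):
            lines.append(f"{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{f:.9f}")
        return "\n".join(lines) + "\n"


def _element_amplitudes(
    array: TransducerArray,
    focus_mm: np.ndarray,
    points_mm: np.ndarray,
    medium: Medium,
    drive: np.ndarray,
    freq_mhz: float,
) -> np.ndarray:
    """Complex field of the focused array at ``points_mm`` (vectorized over
    points, looped over elements to bound memory)."""
    k = medium.wavenumber_rad_mm(freq_mhz)
    alpha = medium.attenuation_db_cm_mhz * freq_mhz / 10.0  # dB per mm
    total = np.zeros(points_mm.shape[0], dtype=complex)
    for e, r_e in enumerate(array.element_positions):
        d = np.linalg.norm(points_mm - r_e, axis=1)
        if np.any(d == 0.0):
            raise SingularGeometryError("evaluation point coincides with an element")
        d_f = np.linalg.norm(focus_mm - r_e)
        if d_f == 0.0:
            raise SingularGeometryError("focus coincides with an element")
        contrib = drive[e] * np.exp(1j * k * (d - d_f)) / d
        if alpha > 0:
            contrib = contrib * 10.0 ** (-alpha * d / 20.0)
        total += contrib
    return total


def simulate_steered_field(
    array: TransducerArray,
    focus_mm,
    medium: Medium | None = None,
    grid: EvaluationGrid | None = None,
    drive: np.ndarray | None = None,
    freq_mhz: float | None = None,
) -> PressureField:
    """Simulate the CW pressure-amplitude field for a focus steered to
    ``focus_mm``.

    Element phases are set so all contributions add coherently at the
    focus; ``drive`` holds per-element real amplitudes (default 1).  The
    returned amplitudes are nonnegative and linear in the drive.
    """
    medium = medium or Medium()
    focus = np.asarray(focus_mm, dtype=float)
    if grid is None:
        grid = EvaluationGrid.around(focus)
    if drive is None:
        drive = np.ones(array.n_elements)
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (array.n_elements,):
        raise InvalidParameterError("drive must have one amplitude per element")
    f = freq_mhz if freq_mhz is not None else array.center_frequency_mhz
    pts = grid.points()
    field = _element_amplitudes(array, focus, pts, medium, drive, f)
    amp = np.abs(field).reshape(grid.shape)
    return PressureField(
        grid=grid, amplitude=amp, frequency_mhz=f, drive=drive, focus_mm=focus
    )


def steered_focus_amplitude(
    array: TransducerArray,
    focus_mm,
    medium: Medium | None = None,
    drive: np.ndarray | None = None,
    freq_mhz: float | None = None,
) -> float:
    """Field amplitude exactly at the steered focus.

    With phase alignment every element contributes ``a_e / d_e`` in phase, so
    this is the coherent on-focus amplitude used as the compensation
    reference.
    """
    medium = medium or Medium()
    focus = np.asarray(focus_mm, dtype=float)
    if drive is None:
        drive = np.ones(array.n_elements)
    field = _element_amplitudes(
        array,
        focus,
        focus[None, :],
        medium,
        np.asarray(drive, dtype=float),
        freq_mhz if freq_mhz is not None else array.center_frequency_mhz,
    )
    return float(np.abs(field[0]))


def compensation_factors(
    array: TransducerArray,
    plan: TreatmentPlan,
    medium: Medium | None = None,
    warn_factor: float = 10.0,
) -> CompensationTable:
    """Per-position drive scale factors equalizing focal pressure over a
    steered grid.

    The reference is the on-focus amplitude at the array's geometric focus
    with unit drives; position i's factor is ``reference / amplitude_i`` so
    that scaling the drives by the factor restores the reference focal
    pressure.  The factor at the geometric focus itself is exactly 1.

    Emits :class:`SteeringRangeWarning` when any factor exceeds
    ``warn_factor`` (focus far outside the array's steering range).
    """
    medium = medium or Medium()
    ref = steered_focus_amplitude(array, array.geometric_focus_mm, medium)
    factors = np.empty(plan.n_positions)
    for i, pos in enumerate(plan.focus_positions_mm):
        amp = steered_focus_amplitude(array, pos, medium)
        factors[i] = ref / amp
    if np.any(factors > warn_factor):
        warnings.warn(
            f"compensation factor exceeds {warn_factor}: steering out of range",
            SteeringRangeWarning,
            stacklevel=2,
        )
    return CompensationTable(
        positions_mm=np.array(plan.focus_positions_mm, dtype=float),
        factors=factors,
        reference_peak=ref,
    )


def _axis_extent(profile: np.ndarray, coords: np.ndarray, peak_idx: int, thresh: float) -> float:
    """Extent of the contiguous above-threshold run around ``peak_idx``,
    with linear interpolation of the crossing positions."""
    n = profile.size
    # Walk right.
    right = coords[-1]
    for i in range(peak_idx, n - 1):
        if profile[i + 1] < thresh:
            frac = (profile[i] - thresh) / (profile[i] - profile[i + 1])
            right = coords[i] + frac * (coords[i + 1] - coords[i])
            break
    # Walk left.
    left = coords[0]
    for i in range(peak_idx, 0, -1):
        if profile[i - 1] < thresh:
            frac = (profile[i] - thresh) / (profile[i] - profile[i - 1])
            left = coords[i] - frac * (coords[i] - coords[i - 1])
            break
    return float(right - left)


def focal_dimensions(
    field: PressureField, threshold_db: float = -6.0
) -> tuple[float, float, float]:
    """Focal extents (z axial, x transverse, y transverse) at a dB threshold.

    Measures, along each principal axis through the global peak, the
    contiguous region where amplitude >= peak * 10**(threshold_db / 20),
    interpolating the crossing points linearly between lattice samples.
    A threshold >= 0 dB selects only the peak itself: returns (0, 0, 0)
    with a warning.
    """
    if threshold_db >= 0:
        warnings.warn("threshold >= 0 dB yields zero extent", UserWarning, stacklevel=2)
        return (0.0, 0.0, 0.0)
    amp = field.amplitude
    i, j, k = np.unravel_index(int(np.argmax(amp)), amp.shape)
    thresh = amp[i, j, k] * 10.0 ** (threshold_db / 20.0)
    ax = _axis_extent(amp[:, j, k], field.grid.x_mm, i, thresh)
    ay = _axis_extent(amp[i, :, k], field.grid.y_mm, j, thresh)
    az = _axis_extent(amp[i, j, :], field.grid.z_mm, k, thresh)
    return (az, ax, ay)
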