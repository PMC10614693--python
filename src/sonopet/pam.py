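"""Passive acoustic mapping (PAM) via the angular spectrum approach.

During each FUS burst the linear imaging array passively records microbubble
emissions.  This module reconstructs, per frequency band, a 2-D map
(lateral x depth, in the imaging plane) of acoustic source intensity:

1. Hann-taper and Fourier-transform each channel's burst record;
2. select the spectral bins inside the requested band;
3. for each selected frequency, treat the per-element complex amplitudes as
   the aperture field, Fourier-transform along the aperture, back-propagate
   to each depth with the angular-spectrum transfer function (evanescent
   components ``k_x^2 > k^2`` are zeroed, not attenuated), inverse-transform;
4. accumulate |field|^2 over frequencies and bursts.

Sign convention: numpy's forward FFT uses ``e^{-2*pi*i*f*t}``, under which a
wave arriving from depth carries phase ``e^{-i k d}``; back-propagation
(phase advance toward the source) is therefore ``exp(+i z sqrt(k^2 - k_x^2))``
here, the conjugate of the ``e^{+i*omega*t}``-convention operator.

The aperture is zero-padded 4x before the spatial transform and the angular
spectrum is further zero-padded (exact band-limited interpolation) so the
lateral pixel pitch reaches the requested value (default 0.1 mm; the
element pitch of a 128-element / 38 mm array is ~0.297 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .exceptions import EmptyBandError, InvalidBandError, InvalidParameterError, NoSignalError
from .synthetic import RFRecording

__all__ = [
    "FrequencyBand",
    "BandSet",
    "PAMImage",
    "harmonic_bands",
    "broadband_bands",
    "default_bandset",
    "asm_pam",
    "localize_max",
    "localization_offset",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A monitoring band [center - bw/2, center + bw/2] (MHz)."""

    center_mhz: float
    bandwidth_mhz: float
    label: str = "harmonic"

    def __post_init__(self) -> None:
        if self.bandwidth_mhz <= 0:
            raise InvalidParameterError("bandwidth must be positive")
        if self.label not in ("harmonic", "ultraharmonic", "broadband"):
            raise InvalidParameterError(f"unknown band label {self.label!r}")

    @property
    def lo_mhz(self) -> float:
        return self.center_mhz - self.bandwidth_mhz / 2.0

    @property
    def hi_mhz(self) -> float:
        return self.center_mhz + self.bandwidth_mhz / 2.0

    def bin_mask(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Closed-interval membership of FFT bins in the band."""
        f_mhz = freqs_hz / 1e6
        return np.abs(f_mhz - self.center_mhz) <= self.bandwidth_mhz / 2.0


def harmonic_bands(
    centers_mhz=(4.5, 6.0, 7.5, 9.0, 10.5), bandwidth_mhz: float = 0.2
) -> list[FrequencyBand]:
    """Harmonic monitoring bands: multiples 3-7 of the 1.5 MHz fundamental
    (4.5 ... 10.5 MHz) at 0.2 MHz bandwidth; stable-cavitation signature."""
    return [FrequencyBand(c, bandwidth_mhz, "harmonic") for c in centers_mhz]


def broadband_bands(
    centers_mhz=(5.25, 6.75, 8.25, 9.75), bandwidth_mhz: float = 1.0
) -> list[FrequencyBand]:
    """Broadband monitoring bands between the harmonics, 1.0 MHz bandwidth;
    inertial-cavitation signature."""
    return [FrequencyBand(c, bandwidth_mhz, "broadband") for c in centers_mhz]


@dataclass(frozen=True)
class BandSet:
    """Named collection of monitoring bands, grouped by label for the
    band-power statistics."""

    bands: tuple[FrequencyBand, ...]

    def by_label(self) -> dict[str, list[FrequencyBand]]:
        out: dict[str, list[FrequencyBand]] = {}
        for b in self.bands:
            out.setdefault(b.label, []).append(b)
        return out

    @property
    def labels(self) -> list[str]:
        return list(self.by_label())


def default_bandset() -> BandSet:
    return BandSet(tuple(harmonic_bands()) + tuple(broadband_bands()))


@dataclass(frozen=True)
class PAMImage:
    """Band-selective acoustic source intensity over the imaging plane.

    ``intensity[i, j]`` is the accumulated |field|^2 at lateral position
    ``lateral_mm[i]`` and depth ``depth_mm[j]`` (mm from the array).
    """

    intensity: np.ndarray
    lateral_mm: np.ndarray
    depth_mm: np.ndarray
    band_label: str
    n_bursts: int

    @property
    def pixel_mm(self) -> tuple[float, float]:
        dl = float(self.lateral_mm[1] - self.lateral_mm[0]) if self.lateral_mm.size > 1 else 0.0
        dz = float(self.depth_mm[1] - self.depth_mm[0]) if self.depth_mm.size > 1 else 0.0
        return (dl, dz)


def _check_uniform_pitch(x: np.ndarray) -> float:
    d = np.diff(x)
    if d.size == 0:
        raise InvalidParameterError("PAM needs at least two elements")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError("imaging array must have uniform pitch")
    return float(d[0])


def _band_bins(bands, freqs_hz: np.ndarray, fs_hz: float) -> np.ndarray:
    nyquist = fs_hz / 2.0
    mask = np.zeros(freqs_hz.size, dtype=bool)
    for b in bands:
        if b.hi_mhz * 1e6 > nyquist or b.lo_mhz < 0:
            raise InvalidBandError(
                f"band {b.center_mhz}+-{b.bandwidth_mhz / 2} MHz outside [0, Nyquist]"
            )
        mask |= b.bin_mask(freqs_hz)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptyBandError("band selects no spectral bins")
    return idx


def asm_pam(
    rf: RFRecording,
    band,
    depth_range_mm: tuple[float, float] = (40.0, 70.0),
    lateral_pixel_mm: float = 0.1,
    axial_pixel_mm: float = 0.25,
    pad_factor: int = 4,
    per_burst: bool = False,
    freq_chunk: int = 64,
):
    """Angular-spectrum PAM of an RF recording for one band (or a list of
    same-label bands).

    Returns a cumulative :class:`PAMImage` over all bursts, or a list of
    per-burst images when ``per_burst`` is true.
    """
    bands = [band] if isinstance(band, FrequencyBand) else list(band)
    label = bands[0].label
    x_elem = rf.element_positions_mm[:, 0]
    pitch = _check_uniform_pitch(x_elem)
    n_elem = rf.n_elements
    n_time = rf.n_time
    fs_hz = rf.sampling_rate_mhz * 1e6
    freqs = np.fft.rfftfreq(n_time, 1.0 / fs_hz)
    bins = _band_bins(bands, freqs, fs_hz)

    z0, z1 = depth_range_mm
    depths = z0 + np.arange(int(np.floor((z1 - z0) / axial_pixel_mm)) + 1) * axial_pixel_mm
    m_pad = pad_factor * n_elem
    upsample = max(1, int(np.ceil(pitch / lateral_pixel_mm)))
    m_fine = m_pad * upsample
    kx = 2.0 * np.pi * np.fft.fftfreq(m_pad, d=pitch)  # rad/mm
    c_mm_s = rf.speed_of_sound_m_s * 1e3
    window = hann(n_time, sym=False)

    # Lateral image coordinates: the aperture occupies the first n_elem*upsample
    # fine samples starting at the first element.
    n_lat = n_elem * upsample
    lateral = x_elem[0] + np.arange(n_lat) * (pitch / upsample)

    k_all = 2.0 * np.pi * freqs[bins] / c_mm_s  # rad/mm per selected bin
    images = []
    accum = np.zeros((n_lat, depths.size))
    for b in range(rf.n_bursts):
        spec = np.fft.rfft(rf.samples[b].astype(np.float64) * window, axis=-1)
        ap = spec[:, bins].T  # (n_sel, n_elem) aperture fields
    # chunked back-propagation over selected frequencies
        burst_img = np.zeros_like(accum)
        for s in range(0, bins.size, freq_chunk):
            sl = slice(s, min(s + freq_chunk, bins.size))
            a_kx = np.fft.fft(ap[sl], n=m_pad, axis=-1)  # (nf, m_pad)
            k = k_all[sl][:, None]  # (nf, 1)
            kz2 = k**2 - kx[None, :] ** 2
            prop_mask = kz2 > 0
            kz = np.sqrt(np.where(prop_mask, kz2, 0.0))
            # (nf, nz, m_pad): back-propagated angular spectrum at each depth
            phase = np.exp(1j * depths[None, :, None] * kz[:, None, :])
            spec_z = a_kx[:, None, :] * phase * prop_mask[:, None, :]
            # exact band-limited lateral interpolation: zero-pad k_x spectrum
            if upsample > 1:
                padded = np.zeros(spec_z.shape[:-1] + (m_fine,), dtype=complex)
                half = m_pad // 2
                padded[..., :half] = spec_z[..., :half]
                padded[..., m_fine - (m_pad - half):] = spec_z[..., half:]
                field = np.fft.ifft(padded, axis=-1) * upsample
            else:
                field = np.fft.ifft(spec_z, axis=-1)
            burst_img += np.einsum(
                "fzx->xz", np.abs(field[..., :n_lat]) ** 2
            )
        if per_burst:
            images.append(
                PAMImage(
                    intensity=burst_img,
                    lateral_mm=lateral,
                    depth_mm=depths,
                    band_label=label,
                    n_bursts=1,
                )
            )
        accum += burst_img
    if per_burst:
        return images
    return PAMImage(
        intensity=accum,
        lateral_mm=lateral,
        depth_mm=depths,
        band_label=label,
        n_bursts=rf.n_bursts,
    )


def localize_max(image: PAMImage) -> tuple[float, float]:
    """Physical (lateral, depth) mm coordinates of the map's peak pixel.

    Ties are broken by first occurrence in row-major (lateral-then-depth)
    scan order.  Raises :class:`NoSignalError` on an all-zero map.
    """
    if not np.any(image.intensity):
        raise NoSignalError("PAM map is all zero")
    i, j = np.unravel_index(int(np.argmax(image.intensity)), image.intensity.shape)
    return (float(image.lateral_mm[i]), float(image.depth_mm[j]))


def localization_offset(
    peak_mm: tuple[float, float], set_focus_mm: tuple[float, float]
) -> tuple[float, float]:
    """Signed (Δlateral, Δaxial) offset of the PAM peak from the set focus."""
    return (peak_mm[0] - set_focus_mm[0], peak_mm[1] - set_focus_mm[1])
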