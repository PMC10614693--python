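"""Seeded generators for every input the pipeline consumes.

Four families of synthetic data, each a pure function of (spec, seed):

* **Cavitation RF** — microbubble acoustic emissions received on the linear
  imaging array during FUS bursts.  Stable cavitation emits discrete
  harmonics of the 1.5 MHz fundamental; inertial cavitation emits
  band-limited broadband noise.  Each channel receives the 1/r-attenuated,
  distance-delayed sum over sources plus white noise.
* **PET phantoms** — 3-D %ID/cc volumes with a focal hotspot (treated
  regime ~2.3-2.5 %ID/cc mean, ~4.3-4.5 %ID/cc max over ~0.3-0.5 %ID/cc
  background), a cardiac blood pool, Gaussian PSF blur and mean-proportional
  Gaussian noise (a reconstructed-image surrogate, not raw Poisson counts),
  together with a truth record of the exact pre-noise ROI statistics.
* **qPCR Ct tables** — target/housekeeping Ct values with configured
  per-group fold changes (target Ct shifted by -log2(fold)).
* **Biodistribution count tables** — gamma counts from configured %ID/g
  truths, organ masses and a counts-per-%ID calibration.

These generators define the study conditions the analysis modules are
tested against; their defaults mirror the in-vivo regimes the pipeline is
meant to quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import AliasingError, InvalidParameterError
from .protocol import BurstSchedule, TransducerArray

__all__ = [
    "CavitationSource",
    "RFRecording",
    "PhantomSpec",
    "TruthRecord",
    "make_cavitation_rf",
    "make_pet_phantom",
    "phantom_as_activity",
    "make_qpcr_ct",
    "make_biodist_table",
    "ISOTOPE_HALF_LIFE_H",
]

# Isotope half-lives (hours); shared with pet_quant.
ISOTOPE_HALF_LIFE_H = {"Cu-64": 12.701, "F-18": 109.77 / 60.0}

DEFAULT_FUNDAMENTAL_MHZ = 1.5
#: Harmonic multiples whose frequencies match the monitored harmonic bands
#: (3..7 x 1.5 MHz = 4.5, 6, 7.5, 9, 10.5 MHz).
DEFAULT_HARMONIC_MULTIPLES = (3, 4, 5, 6, 7)
DEFAULT_HARMONIC_RATIO = 0.7
DEFAULT_BROADBAND_MHZ = (3.0, 12.0)


def default_harmonic_amplitudes(
    multiples=DEFAULT_HARMONIC_MULTIPLES, ratio: float = DEFAULT_HARMONIC_RATIO
) -> dict[int, float]:
    """Geometrically decaying relative amplitudes per harmonic multiple."""
    return {m: ratio**i for i, m in enumerate(multiples)}


@dataclass(frozen=True)
class CavitationSource:
    """A point cavitation source in the imaging plane.

    ``kind`` controls the emission: "stable" -> harmonics only,
    "inertial" -> broadband only, "mixed" -> both.  ``burst_amplitudes``
    optionally scales the emission per burst (e.g. a ramp);
    ``active_bursts`` restricts emission to a subset of burst indices.
    """

    position_mm: tuple[float, float, float] = (0.0, 0.0, 55.0)
    kind: str = "stable"
    fundamental_mhz: float = DEFAULT_FUNDAMENTAL_MHZ
    harmonic_amplitudes: dict[int, float] = field(default_factory=default_harmonic_amplitudes)
    broadband_level: float = 0.0
    broadband_mhz: tuple[float, float] = DEFAULT_BROADBAND_MHZ
    amplitude: float = 1.0
    active_bursts: frozenset[int] | None = None
    burst_amplitudes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "inertial", "mixed"):
            raise InvalidParameterError(f"unknown source kind {self.kind!r}")
        if self.kind == "stable" and self.broadband_level != 0.0:
            raise InvalidParameterError("stable sources must have broadband_level = 0")
        if self.kind == "inertial" and self.broadband_level <= 0.0:
            raise InvalidParameterError("inertial sources need broadband_level > 0")

    def max_frequency_mhz(self) -> float:
        f = 0.0
        if self.kind in ("stable", "mixed") and self.harmonic_amplitudes:
            f = max(self.harmonic_amplitudes) * self.fundamental_mhz
        if self.kind in ("inertial", "mixed"):
            f = max(f, self.broadband_mhz[1])
        return f

    def emits_in(self, burst: int) -> bool:
        return self.active_bursts is None or burst in self.active_bursts

    def scale_at(self, burst: int) -> float:
        s = self.amplitude
        if self.burst_amplitudes is not None:
            s *= self.burst_amplitudes[burst]
        return s


@dataclass(frozen=True)
class RFRecording:
    """Per-element, per-burst passive RF from the imaging array.

    ``samples`` has shape (n_bursts, n_elements, n_time), float32.
    """

    samples: np.ndarray
    sampling_rate_mhz: float
    element_positions_mm: np.ndarray
    burst_times_s: np.ndarray
    focus_index: np.ndarray
    pressure_kpa: float = float("nan")
    speed_of_sound_m_s: float = 1540.0
    seed: int | None = None
    animal_id: str | None = None

    @property
    def n_bursts(self) -> int:
        return self.samples.shape[0]

    @property
    def n_elements(self) -> int:
        return self.samples.shape[1]

    @property
    def n_time(self) -> int:
        return self.samples.shape[2]

    def scaled(self, s: float) -> "RFRecording":
        return replace(self, samples=self.samples * np.float32(s))


def make_cavitation_rf(
    sources: list[CavitationSource],
    array: TransducerArray,
    n_bursts: int = 1,
    sampling_rate_mhz: float = 62.5,
    duration_ms: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    schedule: BurstSchedule | None = None,
    speed_of_sound_m_s: float = 1540.0,
    pressure_kpa: float = float("nan"),
    animal_id: str | None = None,
) -> RFRecording:
    """Synthesize passive RF recordings of cavitation emissions.

    Each element's burst record is the sum over sources of the source
    emission delayed by distance/c and attenuated by 1/r, plus white
    Gaussian noise with standard deviation ``noise_sd`` relative to the RMS
    of the clean signal.  Harmonic components are steady-state sinusoids
    (delays enter as exact phase shifts); broadband components are
    band-limited white noise delayed in the frequency domain.  Output is
    bit-identical for identical arguments and seed.

    ``schedule`` (if given) supplies burst times and per-burst focus
    indices; ``n_bursts`` caps how many entries are synthesized.
    """
    if schedule is not None:
        n_bursts = min(n_bursts, schedule.n_bursts) if n_bursts else schedule.n_bursts
        burst_times = schedule.times_s[:n_bursts]
        focus_index = schedule.grid_indices[:n_bursts]
    else:
        burst_times = np.arange(n_bursts) * (duration_ms / 1000.0)
        focus_index = np.zeros(n_bursts, dtype=int)
    if n_bursts < 1:
        raise InvalidParameterError("need at least one burst")
    fmax = max((s.max_frequency_mhz() for s in sources), default=0.0)
    if sampling_rate_mhz <= 2.0 * fmax:
        raise AliasingError(
            f"sampling rate {sampling_rate_mhz} MHz cannot represent content up to "
            f"{fmax} MHz (need > {2 * fmax} MHz)"
        )
    fs_hz = sampling_rate_mhz * 1e6
    n_time = int(round(duration_ms * 1e-3 * fs_hz))
    t = np.arange(n_time) / fs_hz
    elem = array.element_positions
    n_elem = elem.shape[0]
    c_mm_s = speed_of_sound_m_s * 1e3

    rng = np.random.default_rng(seed)
    clean = np.zeros((n_bursts, n_elem, n_time), dtype=np.float64)
    freqs = np.fft.rfftfreq(n_time, 1.0 / fs_hz)

    for src in sources:
        pos = np.asarray(src.position_mm, dtype=float)
        d_mm = np.linalg.norm(elem - pos, axis=1)
        if np.any(d_mm == 0.0):
            raise InvalidParameterError("source coincides with an array element")
        tau = d_mm / c_mm_s  # seconds
        # One phase per harmonic per source, fixed across bursts (steady drive).
        phases = {m: rng.uniform(0, 2 * np.pi) for m in sorted(src.harmonic_amplitudes)}
        for b in range(n_bursts):
            if not src.emits_in(b):
                continue
            scale = src.scale_at(b)
            if src.kind in ("stable", "mixed"):
                for m, a in sorted(src.harmonic_amplitudes.items()):
                    f_hz = m * src.fundamental_mhz * 1e6
                    arg = 2 * np.pi * f_hz * (t[None, :] - tau[:, None]) + phases[m]
                    clean[b] += (scale * a / d_mm)[:, None] * np.sin(arg)
            if src.kind in ("inertial", "mixed"):
                white = rng.normal(0.0, src.broadband_level, n_time)
                spec = np.fft.rfft(white)
                lo, hi = (f * 1e6 for f in src.broadband_mhz)
                spec[(freqs < lo) | (freqs > hi)] = 0.0
                shifted = spec[None, :] * np.exp(-2j * np.pi * freqs[None, :] * tau[:, None])
                clean[b] += scale * np.fft.irfft(shifted, n=n_time) / d_mm[:, None]

    if noise_sd > 0:
        rms = float(np.sqrt(np.mean(clean**2)))
        sd = noise_sd * rms if rms > 0 else noise_sd
        clean += rng.normal(0.0, sd, clean.shape)

    return RFRecording(
        samples=clean.astype(np.float32),
        sampling_rate_mhz=sampling_rate_mhz,
        element_positions_mm=elem.copy(),
        burst_times_s=np.asarray(burst_times, dtype=float),
        focus_index=np.asarray(focus_index, dtype=int),
        pressure_kpa=pressure_kpa,
        speed_of_sound_m_s=speed_of_sound_m_s,
        seed=seed,
        animal_id=animal_id,
    )


# ---------------------------------------------------------------------------
# PET phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a quantitative PET phantom (all values %ID/cc).

    The hotspot is an ellipsoid with a radially decaying profile
    ``bg + c * (1 - rho^2)**p``; the exponent is solved so the ROI mean and
    maximum match ``hotspot_mean`` / ``hotspot_max`` exactly before blur and
    noise.  Defaults place a ~10.3 mm^3 treated ROI in the regime of the
    capsid-accumulation study (mean 2.5, max 4.5 over 0.4 background).
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    background: float = 0.4
    hotspot_center_mm: tuple[float, float, float] | None = None
    hotspot_extent_mm: tuple[float, float, float] = (2.7, 2.7, 2.7)
    hotspot_mean: float = 2.5
    hotspot_max: float | None = 4.5
    blood_pool_center_mm: tuple[float, float, float] | None = None
    blood_pool_extent_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    blood_value: float = 1.0
    psf_sigma_mm: float = 0.8
    noise_scale: float = 0.0
    injected_dose_mbq: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background, self.hotspot_mean, self.blood_value) < 0:
            raise InvalidParameterError("concentrations must be nonnegative")
        if self.hotspot_max is not None and self.hotspot_max < self.hotspot_mean:
            raise InvalidParameterError("hotspot_max must be >= hotspot_mean")
        if self.psf_sigma_mm < 0 or self.noise_scale < 0:
            raise InvalidParameterError("psf_sigma and noise_scale must be nonnegative")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one generated phantom (artifact plumbing).

    ROI statistics are recorded pre- and post-blur, both noise-free;
    ``total_percent_id`` is the voxel-sum of %ID/cc x voxel volume of the
    noise-free blurred volume.
    """

    spec: PhantomSpec
    seed: int
    roi_mean_pre: dict[str, float]
    roi_max_pre: dict[str, float]
    roi_mean_post: dict[str, float]
    roi_max_post: dict[str, float]
    blood_value: float
    total_percent_id: float


def _ellipsoid_rho2(spec_shape, voxel, center_mm, extent_mm) -> np.ndarray:
    axes = [
        (np.arange(n) + 0.5) * v for n, v in zip(spec_shape, voxel)
    ]  # voxel-center coordinates, mm
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    a = [max(e / 2.0, 1e-9) for e in extent_mm]
    return (
        ((X - center_mm[0]) / a[0]) ** 2
        + ((Y - center_mm[1]) / a[1]) ** 2
        + ((Z - center_mm[2]) / a[2]) ** 2
    )


def _solve_profile_exponent(s2: np.ndarray, target_ratio: float) -> float:
    """Solve p so that mean((1-rho^2)^p)/max(...) over the mask equals the
    target (mean-bg)/(max-bg) ratio; bisection on the discrete mask."""
    base = 1.0 - s2

    def ratio(p):
        prof = base**p
        return float(prof.mean() / prof.max())

    lo, hi = 1e-3, 60.0
    if ratio(lo) < target_ratio:
        return lo
    if ratio(hi) > target_ratio:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ratio(mid) > target_ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_pet_phantom(spec: PhantomSpec):
    """Generate (volume %ID/cc, ROI masks, truth record) from a spec.

    Masks: ``treated`` (hotspot ellipsoid), ``contralateral`` (its mirror
    through the volume's x mid-plane) and, when a blood pool is configured,
    ``cardiac_blood``.  Raises if the hotspot extends outside the volume.

    Returns the volume as a plain float64 array in %ID/cc; wrap it with
    :func:`sonopet.pet_quant.PETVolume` (units "%ID/cc") for analysis, or
    convert to an activity volume with :func:`phantom_as_activity`.
    """
    shape, voxel = spec.shape, spec.voxel_mm
    fov = [n * v for n, v in zip(shape, voxel)]
    center = (
        spec.hotspot_center_mm
        if spec.hotspot_center_mm is not None
        else (0.65 * fov[0], 0.5 * fov[1], 0.5 * fov[2])
    )
    half = [e / 2.0 for e in spec.hotspot_extent_mm]
    for c, h, f in zip(center, half, fov):
        if c - h < 0 or c + h > f:
            raise InvalidParameterError("hotspot extends outside the volume")

    vol = np.full(shape, float(spec.background))
    rho2 = _ellipsoid_rho2(shape, voxel, center, spec.hotspot_extent_mm)
    inside = rho2 < 1.0
    if not inside.any():
        raise InvalidParameterError("hotspot contains no voxel centers")

    s2 = rho2[inside]
    if spec.hotspot_max is None or spec.hotspot_max == spec.hotspot_mean:
        vol[inside] = spec.hotspot_mean
        peak = spec.hotspot_mean
    else:
        tr = (spec.hotspot_mean - spec.background) / (spec.hotspot_max - spec.background)
        p = _solve_profile_exponent(s2, tr)
        prof = (1.0 - s2) ** p
        c_amp = (spec.hotspot_max - spec.background) / prof.max()
        vol[inside] = spec.background + c_amp * prof
        peak = spec.hotspot_max

    masks: dict[str, np.ndarray] = {"treated": inside}
    mirror_center = (fov[0] - center[0], center[1], center[2])
    masks["contralateral"] = (
        _ellipsoid_rho2(shape, voxel, mirror_center, spec.hotspot_extent_mm) < 1.0
    )

    if spec.blood_pool_center_mm is not None:
        brho2 = _ellipsoid_rho2(shape, voxel, spec.blood_pool_center_mm, spec.blood_pool_extent_mm)
        bp = brho2 < 1.0
        vol[bp] = spec.blood_value
        masks["cardiac_blood"] = bp

    def roi_stats(v):
        return (
            {k: float(v[m].mean()) for k, m in masks.items()},
            {k: float(v[m].max()) for k, m in masks.items()},
        )

    mean_pre, max_pre = roi_stats(vol)

    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / v for v in voxel]
        blurred = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)
    else:
        blurred = vol.copy()
    mean_post, max_post = roi_stats(blurred)

    voxel_cc = np.prod(voxel) / 1000.0  # mm^3 -> cc
    truth = TruthRecord(
        spec=spec,
        seed=spec.seed,
        roi_mean_pre=mean_pre,
        roi_max_pre=max_pre,
        roi_mean_post=mean_post,
        roi_max_post=max_post,
        blood_value=float(spec.blood_value),
        total_percent_id=float(blurred.sum() * voxel_cc),
    )

    out = blurred
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sd = np.sqrt(spec.noise_scale * np.clip(blurred, 0.0, None))
        out = blurred + rng.normal(0.0, 1.0, shape) * sd
    _ = peak
    return out, masks, truth


def phantom_as_activity(
    vol_pct_id_cc: np.ndarray,
    injected_dose_bq: float,
    isotope: str,
    acquisition_time_h: float,
) -> np.ndarray:
    """Convert a %ID/cc phantom to measured activity concentration (Bq/cc)
    at ``acquisition_time_h`` post injection (applies physical decay)."""
    if isotope not in ISOTOPE_HALF_LIFE_H:
        raise InvalidParameterError(f"unknown isotope {isotope!r}")
    decay = 2.0 ** (-acquisition_time_h / ISOTOPE_HALF_LIFE_H[isotope])
    return vol_pct_id_cc / 100.0 * injected_dose_bq * decay


# ---------------------------------------------------------------------------
# qPCR and biodistribution tables
# ---------------------------------------------------------------------------


def make_qpcr_ct(
    group_fold_changes: dict[str, float],
    base_ct_target: float = 28.0,
    base_ct_housekeeping: float = 18.0,
    noise_sd: float = 0.0,
    n_per_group: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a Ct table with configured per-group target fold changes.

    Fold changes are relative to a reference whose configured fold is 1:
    the target-gene Ct in group g is ``base_ct_target - log2(fold_g)`` plus
    noise; housekeeping Ct is unshifted.  Columns: sample_id, group, gene
    ("target" | "housekeeping"), ct.
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if any(f <= 0 for f in group_fold_changes.values()):
        raise InvalidParameterError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in group_fold_changes.items():
        shift = np.log2(fold)
        for i in range(n_per_group):
            sid = f"{group}_{i:02d}"
            ct_t = base_ct_target - shift + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            ct_h = base_ct_housekeeping + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append({"sample_id": sid, "group": group, "gene": "target", "ct": ct_t})
            rows.append({"sample_id": sid, "group": group, "gene": "housekeeping", "ct": ct_h})
    df = pd.DataFrame(rows)
    if (df["ct"] <= 0).any():
        raise InvalidParameterError("generated Ct values must be positive; raise base Ct")
    return df


def make_biodist_table(
    organ_ids: list[str],
    true_pct_id_per_g: dict[str, float],
    masses_g: dict[str, float],
    counts_per_pct_id: float = 1e4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a gamma-counting biodistribution table.

    counts = %ID/g x mass_g x counts_per_%ID x (1 + noise).  Columns:
    organ, mass_g, counts, true_pct_id_per_g.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for organ in organ_ids:
        mass = masses_g[organ]
        if mass <= 0:
            raise InvalidParameterError(f"organ {organ!r} has non-positive mass")
        pct = true_pct_id_per_g[organ]
        eps = rng.normal(0, noise_sd) if noise_sd else 0.0
        rows.append(
            {
                "organ": organ,
                "mass_g": mass,
                "counts": pct * mass * counts_per_pct_id * (1.0 + eps),
                "true_pct_id_per_g": pct,
            }
        )
    return pd.DataFrame(rows)
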