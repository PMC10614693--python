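"""Band-power cavitation metrics.

The monitoring statistic is the band power

    PS_F(t_b) = sum_{f in F} sum_n |S(f, n, t_b)|^2,

where S is the (Hann-tapered) Fourier transform of element n's RF record
for the burst at treatment time t_b and F is a set of monitoring-band bins
— harmonics of the 1.5 MHz drive for stable cavitation, the interleaved
broadband bands for inertial cavitation.  Traces of PS_F versus treatment
time are averaged over animals within a pressure group and over the
recorded focus positions, and the harmonic/broadband power ratio summarizes
whether an exposure was stable-dominated.

Normalization: the one-sided spectrum is scaled so that the sum of PS over
*all* bins equals the time-domain energy of the windowed record (Parseval
consistency).  Every downstream use is a ratio or comparison, so the
choice of normalization is inert; it makes the spectral sums physically
interpretable and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .exceptions import AlignmentError, EmptyBandError, InvalidBandError, NoSignalError
from .pam import BandSet, FrequencyBand, default_bandset
from .synthetic import RFRecording

__all__ = [
    "SpectrumTrace",
    "GroupAverageTrace",
    "CavitationSummary",
    "band_power",
    "trace",
    "average_traces",
    "stable_inertial_summary",
    "traces_to_frame",
]


@dataclass(frozen=True)
class SpectrumTrace:
    """PS_F versus treatment time for one band label of one recording."""

    band_label: str
    values: np.ndarray
    burst_times_s: np.ndarray
    animal_id: str | None = None
    focus_index: int | None = None
    pressure_kpa: float = float("nan")

    def scaled(self, s: float) -> "SpectrumTrace":
        return replace(self, values=self.values * s)


@dataclass(frozen=True)
class GroupAverageTrace:
    """Pointwise mean PS_F trace over (animal x focus position) members of
    one pressure group."""

    pressure_kpa: float
    band_label: str
    values: np.ndarray
    burst_times_s: np.ndarray
    n_traces: int


@dataclass(frozen=True)
class CavitationSummary:
    """Per-burst harmonic/broadband ratio and a stable-vs-inertial call.

    ``ratio`` uses +inf where broadband power is zero but harmonic power is
    not, and NaN where both are zero (``no_signal`` marks those bursts).
    """

    ratio: np.ndarray
    classification: str
    no_signal: np.ndarray
    threshold: float
    stable_fraction_required: float


def _spectrum_power_per_bin(x: np.ndarray, window: np.ndarray) -> np.ndarray:
    """One-sided power per bin, summed over elements, Parseval-normalized.

    ``x`` is (n_elements, n_time).  Returns P[k] with sum_k P[k] equal to
    sum over elements and samples of (window * x)^2.
    """
    n = x.shape[-1]
    spec = np.fft.rfft(x * window, axis=-1)
    p = np.abs(spec) ** 2 / n
    scale = np.full(p.shape[-1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return (p * scale).sum(axis=0)


def band_power(
    rf: RFRecording, bands: BandSet | None = None, burst_index: int = 0
) -> dict[str, float]:
    """PS_F of one burst for every band label in ``bands``.

    Bands sharing a label (the five harmonic bands, the four broadband
    bands) are accumulated into one PS value per label, mirroring the use
    of F as the whole harmonic (or broadband) frequency set.
    """
    bands = bands or default_bandset()
    n = rf.n_time
    window = hann(n, sym=False)
    freqs = np.fft.rfftfreq(n, 1e-6 / rf.sampling_rate_mhz)
    power = _spectrum_power_per_bin(rf.samples[burst_index].astype(np.float64), window)
    out: dict[str, float] = {}
    for label, members in bands.by_label().items():
        mask = np.zeros(freqs.size, dtype=bool)
        for b in members:
            if b.hi_mhz * 1e6 > rf.sampling_rate_mhz * 1e6 / 2.0:
                raise InvalidBandError(f"band {b.center_mhz} MHz beyond Nyquist")
            mask |= b.bin_mask(freqs)
        if not mask.any():
            raise EmptyBandError(f"label {label!r} selects no spectral bins")
        out[label] = float(power[mask].sum())
    return out


def single_band_power(rf: RFRecording, band: FrequencyBand, burst_index: int = 0) -> float:
    """PS of a single band for one burst."""
    return band_power(rf, BandSet((band,)), burst_index)[band.label]


def trace(
    rf: RFRecording,
    bands: BandSet | None = None,
    animal_id: str | None = None,
    focus_index: int | None = None,
) -> dict[str, SpectrumTrace]:
    """PS_F versus treatment time: one value per recorded burst, per label."""
    bands = bands or default_bandset()
    n = rf.n_time
    window = hann(n, sym=False)
    freqs = np.fft.rfftfreq(n, 1e-6 / rf.sampling_rate_mhz)
    masks: dict[str, np.ndarray] = {}
    for label, members in bands.by_label().items():
        mask = np.zeros(freqs.size, dtype=bool)
        for b in members:
            mask |= b.bin_mask(freqs)
        if not mask.any():
            raise EmptyBandError(f"label {label!r} selects no spectral bins")
        masks[label] = mask
    values = {label: np.empty(rf.n_bursts) for label in masks}
    for b in range(rf.n_bursts):
        power = _spectrum_power_per_bin(rf.samples[b].astype(np.float64), window)
        for label, mask in masks.items():
            values[label][b] = power[mask].sum()
    return {
        label: SpectrumTrace(
            band_label=label,
            values=vals,
            burst_times_s=rf.burst_times_s.copy(),
            animal_id=animal_id if animal_id is not None else rf.animal_id,
            focus_index=focus_index,
            pressure_kpa=rf.pressure_kpa,
        )
        for label, vals in values.items()
    }


def average_traces(traces: list[SpectrumTrace]) -> dict[float, GroupAverageTrace]:
    """Unweighted pointwise mean of member traces, grouped by pressure.

    Mirrors the group averaging over animals in the same pressure group and
    over the recorded focus positions.  All member traces of a group must
    share the burst-time grid.
    """
    if not traces:
        raise NoSignalError("no traces to average")
    groups: dict[float, list[SpectrumTrace]] = {}
    for tr in traces:
        groups.setdefault(float(tr.pressure_kpa), []).append(tr)
    out = {}
    for pressure, members in groups.items():
        ref_t = members[0].burst_times_s
        for m in members[1:]:
            if m.burst_times_s.shape != ref_t.shape or not np.allclose(
                m.burst_times_s, ref_t
            ):
                raise AlignmentError("member traces do not share a burst grid")
        labels = {m.band_label for m in members}
        if len(labels) > 1:
            raise AlignmentError("cannot average traces of different bands")
        stacked = np.vstack([m.values for m in members])
        out[pressure] = GroupAverageTrace(
            pressure_kpa=pressure,
            band_label=members[0].band_label,
            values=stacked.mean(axis=0),
            burst_times_s=ref_t.copy(),
            n_traces=len(members),
        )
    return out


def stable_inertial_summary(
    harmonic_trace: SpectrumTrace,
    broadband_trace: SpectrumTrace,
    threshold: float = 10.0,
    stable_fraction_required: float = 0.9,
) -> CavitationSummary:
    """Per-burst harmonic/broadband power ratio and a stable-vs-inertial
    classification.

    An exposure is called "stable-dominated" when the ratio exceeds
    ``threshold`` (a repository default, not a literature calibration) for
    at least ``stable_fraction_required`` of the bursts with signal.
    """
    h, bb = harmonic_trace.values, broadband_trace.values
    if h.shape != bb.shape or not np.allclose(
        harmonic_trace.burst_times_s, broadband_trace.burst_times_s
    ):
        raise AlignmentError("harmonic and broadband traces are not aligned")
    no_signal = (h == 0) & (bb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(no_signal, np.nan, np.where(bb == 0, np.inf, h / bb))
    valid = ~no_signal
    if not valid.any():
        classification = "no-signal"
    else:
        frac = float(np.mean(ratio[valid] > threshold))
        classification = (
            "stable-dominated" if frac >= stable_fraction_required else "inertial-component"
        )
    return CavitationSummary(
        ratio=ratio,
        classification=classification,
        no_signal=no_signal,
        threshold=threshold,
        stable_fraction_required=stable_fraction_required,
    )


def traces_to_frame(traces: list[SpectrumTrace]) -> pd.DataFrame:
    """Long-format table (burst_time_s, band, value, animal_id,
    focus_index, pressure_kpa) for CSV export."""
    rows = []
    for tr in traces:
        for t, v in zip(tr.burst_times_s, tr.values):
            rows.append(
                {
                    "burst_time_s": t,
                    "band": tr.band_label,
                    "value": v,
                    "animal_id": tr.animal_id,
                    "focus_index": tr.focus_index,
                    "pressure_kpa": tr.pressure_kpa,
                }
            )
    return pd.DataFrame(rows)
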