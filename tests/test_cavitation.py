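"""Band-power statistic PS_F: Parseval consistency, band isolation,
traces, group averaging and stable-vs-inertial summaries."""

import numpy as np
import pytest
from scipy.signal.windows import hann

from sonopet import cavitation, pam, synthetic
from sonopet.exceptions import AlignmentError, EmptyBandError
from tests.conftest import toy_linear_array


def tone_rf(f_mhz=6.0, n_elem=4, n_time=1000, fs_mhz=25.0, amplitude=1.0):
    """Direct-construction RF: the same pure tone on every channel."""
    t = np.arange(n_time) / (fs_mhz * 1e6)
    x = amplitude * np.sin(2 * np.pi * f_mhz * 1e6 * t)
    samples = np.broadcast_to(x, (1, n_elem, n_time)).astype(np.float32).copy()
    arr = toy_linear_array(n_elem, 1.0)
    return synthetic.RFRecording(
        samples=samples,
        sampling_rate_mhz=fs_mhz,
        element_positions_mm=arr.element_positions,
        burst_times_s=np.array([0.0]),
        focus_index=np.array([0]),
    )


def windowed_energy(rf, burst=0):
    """Independent time-domain oracle: sum over elements and samples of the
    Hann-windowed signal squared."""
    w = hann(rf.n_time, sym=False)
    return float(((rf.samples[burst].astype(float) * w) ** 2).sum())


class TestBandPower:
    def test_pure_tone_power_captured_by_its_band(self):
        """PS in the 6.0-center harmonic band equals the windowed tone energy
        within 1%; every broadband band holds < 1% of it."""
        rf = tone_rf(6.0)
        bands = pam.BandSet(
            (pam.FrequencyBand(6.0, 0.2, "harmonic"),)
            + tuple(pam.broadband_bands((5.25, 6.75, 8.25, 9.75)))
        )
        ps = cavitation.band_power(rf, bands)
        assert ps["harmonic"] == pytest.approx(windowed_energy(rf), rel=0.01)
        assert ps["broadband"] < 0.01 * ps["harmonic"]

    def test_quadratic_amplitude_scaling(self):
        rf1, rf2 = tone_rf(6.0, amplitude=1.0), tone_rf(6.0, amplitude=2.0)
        band = pam.BandSet((pam.FrequencyBand(6.0, 0.2, "harmonic"),))
        p1 = cavitation.band_power(rf1, band)["harmonic"]
        p2 = cavitation.band_power(rf2, band)["harmonic"]
        assert p2 == pytest.approx(4.0 * p1, rel=1e-6)

    def test_parseval_consistency_over_full_spectrum(self):
        """PS summed over a band covering all bins equals the time-domain
        energy of the windowed record."""
        rng = np.random.default_rng(0)
        arr = toy_linear_array(4, 1.0)
        samples = rng.normal(0, 1, (1, 4, 1000)).astype(np.float32)
        rf = synthetic.RFRecording(
            samples=samples, sampling_rate_mhz=25.0,
            element_positions_mm=arr.element_positions,
            burst_times_s=np.array([0.0]), focus_index=np.array([0]),
        )
        nyq = rf.sampling_rate_mhz / 2
        full = pam.BandSet((pam.FrequencyBand(nyq / 2, nyq, "broadband"),))
        ps = cavitation.band_power(rf, full)["broadband"]
        assert ps == pytest.approx(windowed_energy(rf), rel=1e-9)

    def test_additivity_over_disjoint_bands(self):
        """PS over the union of two disjoint bands equals the sum of the
        individual PS values."""
        rf = tone_rf(6.0)
        df = rf.sampling_rate_mhz / rf.n_time  # 0.025 MHz bin spacing
        # boundaries placed between bins so no bin is shared or dropped
        lo = pam.FrequencyBand(5.9 + df / 4, 0.2, "harmonic")
        hi = pam.FrequencyBand(6.1 + 3 * df / 4, 0.2, "harmonic")
        union = pam.FrequencyBand(6.0 + df / 2, 0.4 + df / 2, "harmonic")
        p_lo = cavitation.single_band_power(rf, lo)
        p_hi = cavitation.single_band_power(rf, hi)
        p_union = cavitation.single_band_power(rf, union)
        assert p_union == pytest.approx(p_lo + p_hi, rel=1e-12)

    def test_empty_band_rejected(self):
        rf = tone_rf(6.0)
        df = rf.sampling_rate_mhz / rf.n_time
        off_bin = pam.BandSet((pam.FrequencyBand((100 + 0.5) * df, 0.2 * df, "harmonic"),))
        with pytest.raises(EmptyBandError):
            cavitation.band_power(rf, off_bin)


class TestTrace:
    def stable_rf(self, n_bursts=5, **kwargs):
        arr = toy_linear_array(4, 2.0)
        src = synthetic.CavitationSource(position_mm=(0.0, 0.0, 30.0), kind="stable", **kwargs)
        return synthetic.make_cavitation_rf(
            [src], arr, n_bursts=n_bursts, duration_ms=0.2, seed=4
        )

    def test_constant_source_gives_flat_trace(self):
        traces = cavitation.trace(self.stable_rf())
        vals = traces["harmonic"].values
        assert vals.max() / vals.min() < 1.01

    def test_trace_nonzero_exactly_in_active_bursts(self):
        rf = self.stable_rf(n_bursts=6, active_bursts=frozenset({2, 3, 4}))
        vals = cavitation.trace(rf)["harmonic"].values
        assert (vals[[2, 3, 4]] > 0).all()
        assert np.allclose(vals[[0, 1, 5]], 0.0)

    def test_amplitude_ramp_gives_monotone_trace(self):
        rf = self.stable_rf(n_bursts=5, burst_amplitudes=(1.0, 1.5, 2.0, 2.5, 3.0))
        vals = cavitation.trace(rf)["harmonic"].values
        assert (np.diff(vals) > 0).all()


class TestAveraging:
    def make_trace(self, values, pressure=600.0, label="harmonic"):
        values = np.asarray(values, dtype=float)
        return cavitation.SpectrumTrace(
            band_label=label, values=values,
            burst_times_s=np.arange(values.size) * 0.2,
            pressure_kpa=pressure,
        )

    def test_single_trace_averages_to_itself(self):
        tr = self.make_trace([1.0, 2.0, 5.0])
        avg = cavitation.average_traces([tr])[600.0]
        assert np.allclose(avg.values, tr.values)
        assert avg.n_traces == 1

    def test_identical_traces_average_unchanged(self):
        tr = self.make_trace([1.0, 2.0, 5.0])
        avg = cavitation.average_traces([tr, tr])[600.0]
        assert np.allclose(avg.values, tr.values)

    def test_hand_computed_mean(self):
        a = self.make_trace([1.0, 2.0, 3.0])
        b = self.make_trace([3.0, 2.0, 1.0])
        avg = cavitation.average_traces([a, b])[600.0]
        assert np.allclose(avg.values, [2.0, 2.0, 2.0])

    def test_groups_kept_separate(self):
        a = self.make_trace([1.0, 1.0], pressure=420.0)
        b = self.make_trace([3.0, 3.0], pressure=740.0)
        out = cavitation.average_traces([a, b])
        assert set(out) == {420.0, 740.0}

    def test_mismatched_burst_grids_rejected(self):
        a = self.make_trace([1.0, 2.0, 3.0])
        b = self.make_trace([1.0, 2.0])
        with pytest.raises(AlignmentError):
            cavitation.average_traces([a, b])

    def test_averaging_commutes_with_amplitude_scaling(self):
        a = self.make_trace([1.0, 2.0, 3.0])
        b = self.make_trace([2.0, 4.0, 8.0])
        avg_then_scale = cavitation.average_traces([a, b])[600.0].values * 4.0
        scale_then_avg = cavitation.average_traces([a.scaled(4.0), b.scaled(4.0)])[600.0].values
        assert np.allclose(avg_then_scale, scale_then_avg)


class TestStableInertialSummary:
    def paired_traces(self, kind, seed=0, level=1.0):
        arr = toy_linear_array(4, 2.0)
        if kind == "stable":
            src = synthetic.CavitationSource(position_mm=(0.0, 0.0, 30.0), kind="stable")
        else:
            src = synthetic.CavitationSource(
                position_mm=(0.0, 0.0, 30.0), kind="inertial",
                broadband_level=level, harmonic_amplitudes={},
            )
        rf = synthetic.make_cavitation_rf([src], arr, n_bursts=3, duration_ms=0.2, seed=seed)
        traces = cavitation.trace(rf)
        return traces["harmonic"], traces["broadband"]

    def test_stable_source_classified_stable_dominated(self):
        h, bb = self.paired_traces("stable")
        summary = cavitation.stable_inertial_summary(h, bb)
        assert summary.classification == "stable-dominated"

    def test_broadband_source_ratio_well_below_one(self):
        """A broadband-only source puts power into the harmonic bands only in
        proportion to their bin width (1 MHz vs 4 MHz total), so the
        harmonic/broadband ratio sits near 0.25 — far below unity."""
        h, bb = self.paired_traces("inertial")
        summary = cavitation.stable_inertial_summary(h, bb)
        assert (summary.ratio[~summary.no_signal] < 0.5).all()
        assert summary.classification == "inertial-component"

    def test_zero_signal_flagged(self):
        z = cavitation.SpectrumTrace("harmonic", np.zeros(3), np.arange(3) * 0.2)
        zb = cavitation.SpectrumTrace("broadband", np.zeros(3), np.arange(3) * 0.2)
        summary = cavitation.stable_inertial_summary(z, zb)
        assert summary.classification == "no-signal"
        assert summary.no_signal.all()
        assert np.isnan(summary.ratio).all()

    def test_zero_broadband_gives_inf_sentinel(self):
        h = cavitation.SpectrumTrace("harmonic", np.array([1.0, 2.0]), np.arange(2) * 0.2)
        bb = cavitation.SpectrumTrace("broadband", np.zeros(2), np.arange(2) * 0.2)
        summary = cavitation.stable_inertial_summary(h, bb)
        assert np.isinf(summary.ratio).all()
        assert summary.classification == "stable-dominated"

    def test_broadband_power_grows_with_source_level_over_seeds(self):
        """Mean broadband PS strictly increases with broadband_level over
        20 seeds (monotone trend of the generator/metric pair)."""
        means = []
        for level in (0.5, 1.0, 2.0):
            vals = [
                self.paired_traces("inertial", seed=s, level=level)[1].values.mean()
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_highest_pressure_group_has_highest_broadband(self):
        """Three-pressure synthetic scenario: with broadband emission growing
        with drive pressure, the 740 kPa group's averaged broadband PS
        exceeds the 420 and 600 kPa groups'."""
        arr = toy_linear_array(4, 2.0)
        traces = []
        for pressure, level in ((420.0, 0.3), (600.0, 0.6), (740.0, 1.2)):
            for animal in range(2):
                src = synthetic.CavitationSource(
                    position_mm=(0.0, 0.0, 30.0), kind="inertial",
                    broadband_level=level, harmonic_amplitudes={},
                )
                rf = synthetic.make_cavitation_rf(
                    [src], arr, n_bursts=2, duration_ms=0.2,
                    seed=int(pressure) + animal, pressure_kpa=pressure,
                )
                traces.append(cavitation.trace(rf)["broadband"])
        groups = cavitation.average_traces(traces)
        assert groups[740.0].values.mean() > groups[600.0].values.mean()
        assert groups[740.0].values.mean() > groups[420.0].values.mean()

    def test_misaligned_traces_rejected(self):
        h = cavitation.SpectrumTrace("harmonic", np.ones(3), np.arange(3) * 0.2)
        bb = cavitation.SpectrumTrace("broadband", np.ones(2), np.arange(2) * 0.2)
        with pytest.raises(AlignmentError):
            cavitation.stable_inertial_summary(h, bb)


def test_traces_to_frame_long_format():
    tr = cavitation.SpectrumTrace(
        "harmonic", np.array([1.0, 2.0]), np.array([0.0, 0.2]),
        animal_id="m1", focus_index=2, pressure_kpa=600.0,
    )
    df = cavitation.traces_to_frame([tr])
    assert list(df.columns) == [
        "burst_time_s", "band", "value", "animal_id", "focus_index", "pressure_kpa"
    ]
    assert len(df) == 2 and df["value"].tolist() == [1.0, 2.0]
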