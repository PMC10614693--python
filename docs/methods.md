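# Methods

This note documents the models implemented in `sonopet`, the parameter
choices behind them, and what the synthetic data do and do not emulate.

## Coordinate and unit conventions

Right-handed coordinates, x lateral (imaging-array long axis), y
elevational, z depth from the therapeutic array face; lengths in mm,
frequencies in MHz, pressures in kPa, times in s (bursts in ms). ROI
concentrations are %ID/cc (imaging) and %ID/g (ex vivo).

## Treatment protocol

The treatment sweeps an electronically steered focus over a planar grid
(default 5×5, 0.5 mm pitch) centered near the 55 mm geometric focus,
optionally tilted (axis-angle; identity by default since a skull-following
tilt is subject-specific). Grid ordering is row-major, left-to-right then
top-to-bottom; the visit order within a sweep is not physically
constrained, so a fixed convention was chosen. The burst schedule visits
every point once per sweep (25 ms for 25 points at 1 ms per burst) and
repeats at the grid repetition rate (5 Hz) for the sonication duration
(2 min), giving `rep_hz × total_s` bursts per point (600). A schedule whose
sweep cannot fit inside one repetition period is rejected.

Dosimetry arithmetic follows the standard definitions: skull derating is a
scalar insertion loss on pressure (20% for murine skull at 1.5 MHz;
420/600/740 kPa free-field → 336/480/592 kPa in brain), the mechanical
index is PNP[MPa]/√(f[MHz]), microbubble dose is count per kg body mass,
and the insonified volume is the product of the grid extents and the axial
focal extent (2.5 × 2.5 × 2.7 mm → 17 mm³ after integer rounding).
Reported values are conventionally rounded — MI to 2 decimals, volumes to
integer mm³, pressures to integer kPa — matching how such protocols are
summarized.

## Field model and drive compensation

A single-frequency continuous-wave Rayleigh point-source superposition:
each element radiates a spherical wave `a_e·exp(ik(|r−r_e|−|r_f−r_e|))/|r−r_e|`
with the drive phase aligning all contributions at the steered focus
(k = 2πf/c; c = 1540 m/s tissue default, 1480 m/s for water-tank work;
attenuation 0 dB/cm/MHz by default — the skull enters only through the
scalar insertion loss in the protocol module). A 1 ms burst at 1.5 MHz
contains ~1500 cycles, so the CW approximation is appropriate for
amplitude-equalization purposes. Element directivity and baffle factors
are ignored.

The therapeutic array's true element layout is not public; the package
ships a deterministic **synthetic** layout (Fibonacci disc over a
spherically curved 50 mm aperture focused at 55 mm, 128 elements) that
reproduces the qualitative focusing behavior. Its −6 dB focal dimensions
(~11 mm axial, ~1.6 mm transverse on a 0.05 mm lattice) are of the right
order for an f≈1 aperture at 1.5 MHz but are not calibrated to any
physical device, and none of the contracts depend on their exact values.

Compensation factors are the ratio of the on-focus coherent amplitude at
the geometric focus to that at each steered position (so the geometric
focus has factor exactly 1); the contract — re-simulated post-compensation
focal peaks within 1% across the grid — is verified by evaluating the field
over a 0.8×0.8×1.6 mm box around each position at 0.1 mm spacing. Factors
above 10 trigger a steering-range warning. Focal dimensions are measured
along the three principal axes through the global peak with linear
interpolation of the threshold crossings (validated against the closed-form
−6 dB width of a separable Gaussian profile, `2σ√(2·ln(1/10^(−6/20)))`).

## Synthetic cavitation RF

Stable cavitation is modeled as steady-state sinusoids at harmonics of the
1.5 MHz fundamental (default multiples 3–7, i.e. 4.5–10.5 MHz, matching the
monitored harmonic bands; relative amplitudes decay geometrically with
ratio 0.7), inertial cavitation as white Gaussian noise band-limited to
3–12 MHz. These source spectra are plausible placeholders — real microbubble
emission spectra depend on bubble size, shell and drive in ways the
generator does not model; the generator's contract is only the band
semantics (harmonics ↔ stable, broadband ↔ inertial) that the mapping and
metric modules consume. Each channel receives the 1/r-attenuated sum over
sources with exact geometric delays (phase shifts for harmonics, frequency-
domain phase ramps for broadband), plus white noise scaled relative to the
clean-signal RMS. Sampling defaults to 62.5 MHz (≳6× the highest harmonic)
with 1 ms records; per-harmonic phases are drawn once per source, broadband
realizations per burst, all from a single seeded generator, so outputs are
bit-identical per (arguments, seed).

## Passive acoustic mapping

Per burst and channel, records are Hann-tapered (leakage control for the
narrow 0.2 MHz bands; the window choice is a repository default) and
Fourier-transformed; bins inside the requested band are back-propagated by
the angular spectrum method: spatial FFT over the aperture (zero-padded
4×), transfer function `exp(+iz√(k²−k_x²))` in numpy's e^{−2πift} FFT
convention (the conjugate of the e^{+iωt}-convention operator), evanescent
components zeroed, inverse FFT, and |field|² accumulated over bins and
bursts. The angular spectrum is zero-padded before the inverse transform —
exact band-limited interpolation — so the lateral pixel reaches the
requested 0.1 mm despite the ~0.297 mm element pitch; the axial pixel is
0.25 mm over a default 40–70 mm depth range. Maps accumulate across bursts
by summation, with a per-burst option. Since the imaging array is 1-D, maps
are 2-D in the imaging plane.

The implementation is cross-checked against an independent oracle: direct
quadrature of the same back-propagation integral (direct DFT of the
aperture field, dense k_x trapezoid quadrature, per-pixel summation), which
agrees at the source pixel within 5% on toy 8-element inputs. Localization
of a synthetic stable source on the 128-element array recovers the true
position within 0.5 mm laterally and 2.0 mm axially — the point-spread
scale of a 38 mm aperture at 4.5–10.5 MHz and ~55 mm depth.

## Band-power metrics

`PS_F(t_b) = Σ_{f∈F} Σ_n |S(f,n,t_b)|²` with one Hann-tapered transform per
burst record (no sub-window averaging). A bin belongs to band F iff
|f_bin − center| ≤ bandwidth/2 (closed interval). The one-sided spectrum is
scaled so the sum over all bins equals the windowed time-domain energy
(Parseval-consistent); every downstream use is a ratio or comparison, so
this normalization is inert but makes the statistic testable against a
time-domain oracle. Bands sharing a label (five harmonic, four broadband)
are pooled into one PS value per label. Group averages are unweighted
pointwise means over member traces (animals × focus positions) sharing a
burst grid. The stable-vs-inertial summary reports the per-burst
harmonic/broadband ratio (+∞ where broadband power is zero, NaN flagged
where both are zero) and calls an exposure stable-dominated when the ratio
exceeds a threshold (default 10 — a repository default, not a physical
calibration) for ≥90% of bursts with signal. Note that a purely broadband
source still yields a ratio near 0.25, the ratio of total harmonic to
broadband bin widths (1 MHz vs 4 MHz).

## PET phantoms and quantification

Phantoms are %ID/cc volumes (default 48³ voxels at 0.4 mm — preclinical
scanner scale): uniform background (default 0.4), an ellipsoidal hotspot
whose radial profile `bg + c(1−ρ²)^p` is solved so the ROI mean and max
match the configured values exactly before blur (defaults 2.5 / 4.5 %ID/cc
over a ~10.3 mm³ treated ROI — the capsid-accumulation regime; a no-FUS
regime uses ~0.5 mean over ~0.3–0.4 background), an optional blood pool,
isotropic Gaussian PSF blur (σ = 0.8 mm, typical preclinical PET; kernel
normalized, so total activity in the interior is conserved), and Gaussian
noise with variance proportional to the local mean — a surrogate for
reconstructed-image noise, deliberately not raw Poisson counts since the
pipeline starts from reconstructed volumes. A truth record carries the
exact pre-noise ROI statistics pre- and post-blur. Recovery contracts are
stated against the post-blur truth: partial-volume loss from the PSF is a
property of the phantom (the blurred treated-ROI mean is substantially
below the configured pre-blur mean for mm-scale hotspots), and
partial-volume correction is out of scope.

Quantification: activity volumes are decay-corrected to injection time
(Cu-64 t½ = 12.701 h, F-18 t½ = 109.77 min) before %ID normalization — the
standard %ID convention; ROI statistics are plain mean/max over masked
voxels on the exact same lattice (no resampling — masks are inputs, mirroring
manual ROI drawing); blood subtraction `roi − v_b·blood` uses v_b = 4% with
the blood value from a cardiac-chamber ROI, applied to both mean and max,
and negative results are returned with a QC flag rather than clamped so
group averages stay unbiased. Fold changes are reported to one decimal.
ΔΔCt uses per-sample ΔCt = Ct_target − Ct_housekeeping, group-mean
differences, and fold = 2^(−ΔΔCt); R² is the squared Pearson correlation of
the OLS fit.

## What passing tests do and do not show

The generators share their geometry, band conventions and noise models with
the analysis modules' assumptions, so passing tests demonstrate internal
correctness (algorithms implement their definitions; estimators recover
generator truth under the configured noise) — not robustness to real
Verasonics RF (element directivity, TGC, reverberation, skull aberration),
real reconstructed PET (scatter, randoms, reconstruction bias), or real
qPCR (efficiency ≠ 2, plate effects). Those effects are deliberately out of
scope.

## Problem sizes and numerics

Default test problem sizes: PAM localization uses single-burst recordings
on the full 128-element array with depth range 45–65 mm (20 seeds);
the oracle cross-check uses 8-element, 256-sample toys; compensation uses a
3×3 grid re-simulated at 0.1 mm; phantom recovery uses 100 seeded 48³
phantoms; ΔΔCt Monte Carlo uses 200 replicate tables. Tie-breaks: PAM peak
ties resolve to the first pixel in row-major order. Degenerate inputs
(all-zero maps, empty masks or bands, zero broadband power, mismatched
lattices or burst grids) raise typed errors or return documented sentinels
rather than propagating NaNs silently.
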