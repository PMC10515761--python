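# Methods

## Data model

An MRS acquisition is a complex array `data[x, y, z, k]` — SVS is
`1×1×1×n` — plus a 4×4 affine mapping 0-based voxel indices to RAS+ world
millimetres at voxel centres, and a small set of sequence parameters:
transmitter frequency `f0` (MHz), spectral width `SW` (Hz), dwell time
`1/SW` (s), echo time (ms), nucleus, and the chemical shift assigned to the
on-resonance bin (`reference_ppm`, default 4.65 ppm — water at body
temperature; acquisitions that reference differently override it). Two tags
are always explicit: the signal domain (`time` | `frequency`) and the water
suppression state (`suppressed` | `unsuppressed`). Operations that require
one domain reject the other, and the suppression tag travels with the data
so a Philips-style dual export can never be quantified against the wrong
payload silently.

On disk this is `<stem>.nii` (native complex128 NIFTI-1), `<stem>.json`
(sidecar with NIFTI-MRS-style keys; unknown keys are preserved verbatim
across read/write so foreign metadata survives a round trip) and, for
frequency-domain volumes, `<stem>.ppm` — one decimal value per line, no
header. The NIFTI sform holds the affine at float32 precision; round-trip
tests compare against that stored precision. Complex NIFTI is readable by
mainstream viewers' magnitude display; no real/imaginary splitting is
needed with nibabel's complex datatype support, so the 5-D fallback pair
encoding was considered and dropped.

## Spectral conventions

The FFT is unitary (`norm="ortho"`) in both directions, so the
round trip is an identity and Parseval's theorem holds bin for bin. After
the transform the zero-frequency bin is shifted to the axis centre and the
axis is reversed: ppm decreases with bin index, the standard MRS display
order, and the `.ppm` file records exactly the order the axis holds. The
axis is `ppm_k = reference_ppm + f_k / f0` with `f_k` the centred FFT bin
frequencies spanning `[-SW/2, +SW/2)`. The axis *span* is defined as
`n × |bin spacing| = SW/f0` (the width including the half-open end), which
is invariant under zero-filling-style changes of `n`; the max−min of the
bin values is one bin width less, as for any half-open FFT grid.

Window selections (`crop_ppm`, the QA window, integrator windows) are
closed intervals `[lo, hi]`, everywhere.

No apodisation, zero-filling, phase or eddy-current correction is applied:
baseline and lineshape modelling are delegated to the downstream fitting
program, and drift/water-removal corrections are out of scope.

The heat-map collapse for orientation checking is
`log(mean_k |Re s_k| + ε)` per voxel with
`ε = 1e-12 × max|Re|` (or 1 for an all-zero volume) purely to keep the log
finite on empty voxels. The absolute value is deliberate: the real part of
a spectrum can be negative, and a signed mean could cancel a bright voxel
to zero, making "log average real amplitude" ill-defined without it.

## Vendor ingestion

Philips MRS DICOM series carry water-suppressed and water-unsuppressed
payloads; Siemens carries suppressed only. `parse_philips` returns both
volumes, tagged, with identical affines, and treats a single-payload
series as a hard error rather than guessing which spectrum it was handed.
The affine is built from the DICOM geometry (position, row/column direction
cosines, spacing): index steps follow the cosines, the slice axis is their
right-handed cross product, and the first two world axes are negated for
the LPS→RAS conversion. Cosines must be orthonormal within 1e-6 and
spacings positive.

Real vendor private-tag dialects are numerous and undocumented, so the
shipped reader speaks a declared fixture dialect (standard geometry and
sequence tags; payloads as little-endian float32 real/imag pairs in a
private block) behind the same interface a production dialect would use.
Because CSI is centimetre-scale, a flipped or transposed conversion is
nearly invisible on anatomy; the executable defence is the asymmetric
orientation phantom whose marked voxel's world coordinate must survive
every conversion path within 1e-6 mm, and whose mismatch statistic must
fire whenever a left-right flip is injected. A symmetric phantom provably
cannot reveal such a flip — the simulator includes that failure mode as a
regression of the *limitation* itself.

## Spatial overlap and tissue weights

All overlap quantities use voxel-centre counting on the high-resolution
grid: each segmentation voxel centre is mapped through
`inv(A_csi) · A_seg` into continuous CSI index space and assigned to the
nearest CSI voxel (ties at .5 round half to even; out-of-grid centres are
"outside"). This matches a regrid-then-iterate workflow, is exact under a
brute-force triple-loop recount (a standing test), and changes by at most
one voxel-volume quantum per CSI voxel when the segmentation resolution is
halved. Polyhedral intersection would be more precise at segmentation-voxel
granularity but is not testable by enumeration and was not adopted.

Brain coverage per CSI voxel is `(# assigned centres with mask=1) / (#
assigned centres)`; the inclusion filter keeps fractions **strictly**
greater than the threshold (default 0.5), so an exactly half-covered voxel
is excluded. Tissue weights take each included voxel's fraction of assigned
centres carrying a tissue label and normalise across the included set to
sum 1 (within 1e-12); normalisation is across voxels, not within-voxel by
volume. The pipeline order is fixed: coverage filter, then QA exclusion,
then weight normalisation over the survivors — weights are always
normalised over the final set. The weighted-average spectrum is the
complex-linear combination `Σ w_v s_v`; its affine keeps the CSI voxel
scale with the translation set to the weight centroid `Σ w_v center_v`,
a defined (if nominal) location for the averaged signal.

## Lipid QA

Dural lipids distort spectra below 2.0 ppm. Each included voxel's real
spectrum is fit with an ordinary least-squares line against ppm over the
closed window [0.2, 1.8] ppm (≥3 bins required) and summarised by the
residual RMSE. The RMSE is invariant to adding any affine-in-ppm component
and scales linearly with signal amplitude — both property-tested. Outliers
are values strictly above the upper Tukey fence `Q3 + 1.5·(Q3 − Q1)`, with
quartiles by linear interpolation between order statistics (type 7).
Only the upper fence is applied: a suspiciously smooth spectrum is not an
artifact signature, and a two-sided rule would discard clean voxels. With
a degenerate (zero) IQR the fence collapses to Q3 and any exceedance,
however tiny, is flagged — a documented edge case of fence rules on
near-constant samples. Only the real part is fit, matching how spectra
are displayed and fit downstream.

On the default phantom conditions (8×8 grids, lipid artifacts at 10× the
metabolite amplitude, complex noise SD ≤ 0.05× amplitude) the procedure's
detection is clean (sensitivity 1.0, false-positive rate 0.0 across seeded
repeats, monotone in artifact amplitude); these operating characteristics
are recomputed, not asserted, by `scripts/acceptance.py`.

## LCModel bridge and the integrator surrogate

The package writes LCModel RAW files (a `$NMID` namelist, then one
`real imaginary` pair per line at 8 significant digits — lossless at that
precision, verified by write→parse) and minimal control files (data path,
`HZPPPM`, `ECHOT`, dwell, points, and the 0.2–4.0 ppm analysis window;
the control file references the RAW by basename since both are written to
the same directory, keeping runs byte-reproducible across output
locations). Output tables are read from a documented CSV dialect
(`metabolite, concentration, percent_sd`); malformed rows are logged with
line numbers and skipped, and implausible values like %SD 999 are parsed
faithfully — filtering is a separate, explicit step. The reliability filter
drops estimates with Cramer-Rao %SD strictly above 20 (20.0 itself
survives), is idempotent and order-preserving, and passes integrator
estimates through with a warning since they carry no %SD.

The built-in integrator — chord-baselined trapezoidal area of Re(s) over a
closed ppm window — exists so the pipeline can be exercised end to end
without the external program. It shares nothing with basis-set fitting and
is not claimed equivalent. Default windows are NAA [1.9, 2.1],
Cr [2.9, 3.1], lactate [1.2, 1.4] ppm; GSH deliberately has none, because
its multiplets overlap Cr and a window area there would quantify the wrong
molecule — requesting one raises an error pointing at basis-fitted output.

Known bias: the windows are round-number approximations, asymmetric about
the true singlet positions (NAA 2.01, Cr 3.03). Because the chord height
falls off as 1/offset², this asymmetry inflates NAA/Cr by ≈4 % at the
default linewidth — verified against a pure-geometry oracle of exact
continuous Lorentzians, independent of the FFT path. Ratio recovery is
therefore specified and tested at 5 %, and ratio *contrasts* between
conditions are unaffected. Centring windows per-peak would remove the bias
but break the simple fixed-window contract; users needing unbiased
concentrations should use LCModel output, which is the point of the bridge.

## Phantom simulator

The signal model is a sum of exponentially damped complex sinusoids,

    s(t_k) = Σ_m A_m · exp(i·2π·f_m·t_k) · exp(−t_k / T2*_m) + noise,

with `f_m = (ppm_m − reference_ppm)·f0`, `t_k = k/SW`, and seeded complex
Gaussian noise. Each term's spectrum is a Lorentzian of half-width
`1/(π·T2*)` Hz, and the exact sampled transform has a geometric-series
closed form evaluated bin by bin in `analytic_spectrum` with no FFT —
the independent oracle for the whole spectral path (agreement ≤1e-6
relative at every bin, noiseless).

Defaults model a 3 T 1H study: `f0 = 127.74` MHz, `SW = 2000` Hz,
`n = 1024`, TE 30 ms, 10 mm CSI voxels (20 mm SVS). Metabolites sit at the
standard singlet shifts — NAA 2.01 (amplitude 1.0), Cr 3.03 (1.0),
Cho 3.20 (0.8), Lac 1.31 (0.5) — with T2* 0.1 s, i.e. ~3 Hz linewidth;
this decays to <1 % within the 0.512 s readout, keeping truncation ringing
negligible, which matters more to window-area oracles than a narrower
line would. Lipid contamination is a 1.30 ppm resonance at 10× amplitude
with 5× shorter T2*; the unsuppressed companion adds water at the
reference shift with amplitude 100. The CSI layout is left-half "WM"
(metabolite amplitudes ×2) and right-half "dGM" (×1), with the matching
segmentation emitted on an aligned grid 4× finer per axis. Identical seeds
reproduce phantoms bit for bit.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: macromolecule/lipid baselines with realistic
lineshapes (no Gaussian/Voigt broadening, Lorentzian only), B0
inhomogeneity and frequency drift, eddy currents, coil combination,
chemical-shift displacement, J-coupled multiplets (every peak is a
singlet), and real vendor private-tag dialects. Detection and recovery
results on phantoms are evidence the *procedures* are implemented
correctly, not estimates of in vivo performance.

## Numerical and interface choices

- Validation (`validate_volume`) never raises; it returns one message per
  violated invariant, each naming the field, so callers can report all
  problems at once. The CLI maps invariant violations to exit 3 and input
  errors to exit 2.
- Quantile rule, tie-breaking (round half to even), closed windows, and
  the strict coverage inequality are all stated in the code and reports so
  independent recomputation matches exactly.
- CLI runs are deterministic: instance UIDs in DICOM fixtures derive from
  the phantom seed, NIFTI outputs are uncompressed (no embedded mtimes),
  and no timestamps are written anywhere.
- Problem sizes in the test and acceptance suites (8×8×1 grids, 512–1024
  spectral points, 20–50 seeded repeats) are chosen so every oracle is
  enumerable and the whole suite runs in seconds while still exercising
  each statistic's operating regime.
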