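# Methods

## Scope and model

`fibralign` quantifies two things from Masson's trichrome histology and
wound-monitoring data:

1. **Fiber co-orientation.** A single per-image alignment coefficient in
   [0, 1] from Fourier-domain orientation analysis of the isolated
   collagen signal, plus a dominant orientation and a collagen area
   fraction.
2. **Healing kinetics.** Contraction/closure percentages per timepoint
   and a one-phase exponential decay fit of the wound-area time course.

The statistics layer wraps the two designs these readouts feed:
donor-paired two-tailed t-tests (matched irradiated/non-irradiated sites)
and Pearson correlation against months since treatment. No multiplicity
correction is applied — the intended use is a handful of planned
comparisons.

## Collagen isolation

sRGB input is converted to CIELAB (D65, standard sRGB companding) via
scikit-image; 16-bit or float input is first rescaled to the 8-bit range
so the Lab magnitudes are calibrated once. Aniline blue collagen has
strongly negative b\*; red cytoplasm has positive a\*. The default
collagen map adds the full a\* channel to the rectified negative b\*
channel and floors at zero:

    C = max(a* + max(−b*, 0), 0).

"Superimposed" admits more than one arithmetic reading, so two
alternatives are kept behind the `mode` switch rather than silently
chosen: `negb_only` (blueness alone) and `negb_minus_posa` (blueness
penalized by redness, which suppresses red cytoplasm at the cost of also
penalizing blue-red mixes). All modes send a neutral background to ≈0 and
are monotone in blueness at fixed a\*. The default follows the additive
reading literally; on synthetic fields all three separate fibers from
background, and the choice is exposed in every provenance record.

## Enhancement

The enhancement chain is deliberately minimal and fully parameterized:
Gaussian smoothing (default σ = 1 px), a linear contrast stretch mapping
the 1st/99th percentiles to 0/1 with clipping, then a hard zero floor
(default 0.1): values below the floor become exactly 0. The floor is not
cosmetic — the density metric counts *non-zero* pixels, so background
must be exactly zero rather than merely dim. A constant map has no
contrast and maps to all zeros. With pass-through parameters
(p_low=0, p_high=100, σ=0, floor=0) the chain is the identity on [0, 1]
data and hence idempotent.

## Angular spectrum and alignment coefficient

The enhanced image is center-cropped to its largest square (equal
frequency resolution on both axes avoids orientation bias),
mean-subtracted, tapered with a separable Hann window (suppresses
edge-discontinuity leakage), and transformed with a 2-D FFT. Power |F|²
is accumulated into 180 angular bins over [0, π) after folding mod π and
rotating by 90°, because spectral energy lies perpendicular to the fiber
axis; the orientation convention is the spatial fiber axis measured from
the image x-axis (in array coordinates, y down). Only frequencies with
radius between 5% and 45% of Nyquist contribute (defaults, configurable):
the inner cut removes residual low-frequency illumination structure, the
outer cut sensor-scale noise. Power rather than amplitude keeps the
statistic quadratic in contrast and insensitive to global intensity
scaling.

The coefficient is the energy-weighted circular resultant length on
doubled angles, R = |Σ E e^{i2θ}|/Σ E — the standard axial-dispersion
statistic, and the unique choice whose extremes match the intended 0–1
calibration: 1 iff all energy shares one axis, 0 for an isotropic
distribution. Resultants below 1e-12 of total energy are snapped to
exactly 0.0: for evenly spaced bins the cancellation Σ e^{i2θ} = 0 is
exact mathematically and the residual is pure float round-off, which must
not read as alignment. The whole-image (global) coefficient is reported,
matching a single per-image index; tiling is out of scope. The dominant
orientation is the halved argument of the same resultant; a balanced
spectrum (resultant ≈ 0) has no defined orientation and raises a
degenerate-spectrum error rather than returning an arbitrary angle.

Density is count(values > 0)/n_pixels on the enhanced image.

## Wound kinetics

contraction(%) = (IW_D0 − IW_t)/IW_D0 × 100, with Δ oriented so
contraction grows as the inner area shrinks (full closure → +100);
closure(%) = area_t/area_D0 × 100 (100 at day 0). On the same area pair
the two are complementary (sum 100).

The decay Y(t) = plateau + (Y0 − plateau)e^{−kt} is fitted by bounded
trust-region least squares (scipy), bounds k ≥ 0, plateau ≥ 0, parameter
tolerance 1e-8. Fits on ≤6 points are initialization-sensitive, so
starting values come from the data: Y0 from the first observation,
plateau from the minimum, and k from the log-linear slope of
Y − 0.99·plateau_init (the 0.99 keeps the subtracted minimum strictly
positive). Non-convergence returns the best iterate flagged
`converged=False` instead of raising. By default the raw area is fitted;
`fit_variable="contraction_complement"` fits 100·IW_t/IW_D0 instead — a
decay from 100 with the same rate — since either variable is a defensible
definition of a "healing curve" and the choice is reported in the output.
The fit is scale-equivariant: rescaling areas rescales Y0 and plateau and
leaves k unchanged.

## Synthetic data: what it emulates and what it does not

The generator draws `n_fibers` straight anti-aliased segments (coverage
clip(w/2 + 0.5 − d, 0, 1) around sub-pixel endpoints, avoiding
axis-aligned raster artifacts that would bias the spectrum) in a
blue-dominant collagen color over a near-white background, optional red
disks as cytoplasm-like distractors, and clipped additive Gaussian noise.
Orientations are axial: φ ~ vonMises(2μ, κ), θ = (φ/2) mod π, so κ spans
isotropic (0) to near-parallel (∞) and the ground-truth alignment is the
circular resultant of the sampled θ. All randomness flows from one
explicit seed (default 0); identical parameters give byte-identical
images.

Defaults represent a dense dermal field: 512² px, 250 fibers of length
120 px and width 3 px, colors (60, 90, 200) collagen on (240, 238, 242)
background — verified at construction to satisfy the isolation contract
(collagen b\* < 0, background |a\*|, |b\*| < 5).

The simulator does **not** emulate nuclei, stain texture, fiber
curvature, illumination gradients, or polarized-light effects. Passing
tests therefore demonstrate that the *measurement chain* is correct and
calibrated on fields with known orientation statistics; they do not
certify stain-specific segmentation quality on real slides, where the
isolation mode and enhancement percentiles may need adjustment.

Wound fixtures are exact decays plus N(0, noise_sd²) noise clipped at 0;
the recovery suite uses Y0=10, plateau 0–2, k=0.8/day, six daily points
and 2% noise — the sampling density of a daily-imaging ex vivo protocol.

## Numerical choices and degenerate inputs

- Constant images have zero band energy and raise a degenerate-image
  error; empty spectra likewise.
- The resultant snap threshold (1e-12 of total energy) and the fit
  tolerance (1e-8) are fixed, not configurable.
- Percentile degeneracy (p_low ≥ p_high), unknown isolation modes and
  out-of-range radial bands are configuration errors raised before any
  computation.
- A paired test on differences with zero variance is degenerate
  (statistic undefined) — except identical vectors, which return t = 0
  exactly. Constant inputs to the correlation are degenerate.
- Batch processing records per-image failures in the results table and
  continues; only a malformed manifest aborts.

## Validation problem sizes

The test suite validates the oracle agreement on a κ-sweep of
{0, 0.5, 1, 2, 4, 8, 16, 100} with 10 seeds per level at 512² (mean
absolute deviation from the ground-truth resultant < 0.1, Spearman rank
correlation 1 on sweep means), rotation invariance at 30°/45°/60°
(coefficient shift < 0.05, orientation shift within ±5° of the applied
angle), and decay-rate recovery over 50 seeds (median relative error of
k < 10% at 2% noise; 1e-4 relative recovery noiseless). Unit tests use
smaller rasters (64–256 px).

## Known limitations

- The global coefficient mixes sub-regions; a slide with two orthogonal
  aligned domains scores low even though each domain is ordered.
- The density fraction depends on the enhancement percentiles; it is an
  internally consistent comparison metric, not an absolute collagen
  volume fraction.
- The additive isolation mode counts strongly red pixels (positive a\*)
  as signal; on cytoplasm-rich sections `negb_minus_posa` may be the
  better choice.
- Decay fits with k near 0 have effectively unbounded half-life
  estimates; the constant-series limit returns k ≈ 0 with half-life ∞.
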