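# fibralign

Quantitative collagen-fiber alignment and wound-healing kinetics for
Masson's trichrome histology.

Dermal scarring and fibrosis reorganize collagen from a basket-weave into
linear, co-oriented bundles. `fibralign` turns a trichrome-stained section
into three numbers a tissue-repair lab can compare across biopsies —
an **alignment coefficient** in [0, 1], a **dominant fiber orientation**,
and a **collagen density** fraction — and complements them with
wound-closure quantification (contraction/closure percentages, one-phase
exponential decay fits of healing time courses) and donor-paired group
statistics. It is aimed at studies that compare matched skin sites, e.g.
previously irradiated (RT⁺) versus non-irradiated (RT⁻) skin of the same
donor.

## The method

**Collagen isolation.** Trichrome renders collagen blue (aniline blue),
so in CIELAB collagen carries strongly negative b\*. The image is
converted sRGB → CIELAB and the collagen map is built by superimposing
the full a\* channel onto the rectified negative b\* channel,

&nbsp;&nbsp;&nbsp;&nbsp;C(x) = max( a\*(x) + max(−b\*(x), 0), 0 ),

with two alternative readings (`negb_only`, `negb_minus_posa`) selectable
by config. The map is Gaussian-smoothed, percentile contrast-stretched to
[0, 1], and floored so background is **exactly** zero.

**Alignment.** Fibers modulate intensity perpendicular to their axis, so
the 2-D power spectrum of an aligned field concentrates orthogonally to
the fiber direction. After mean subtraction and a Hann taper, |F|² is
accumulated over an annular frequency band into angular bins E(θ) on
[0, π) (rotated 90° into the spatial convention). The coefficient is the
energy-weighted circular resultant length on doubled angles — fibers are
axes, so θ and θ+π are identified:

&nbsp;&nbsp;&nbsp;&nbsp;R = |Σₖ Eₖ e^{i2θₖ}| / Σₖ Eₖ ∈ [0, 1],

exactly 1 for a perfectly aligned field and exactly 0 for a random
(isotropic) one. Density is the fraction of non-zero pixels in the
enhanced image.

**Kinetics.** With IW_t the area inside the initial wound edge,
contraction(%) = (IW_D0 − IW_t)/IW_D0 × 100 and
closure(%) = area_t/area_D0 × 100. Healing time courses are fitted with
the one-phase decay Y(t) = plateau + (Y0 − plateau)·e^{−kt}
(bounded nonlinear least squares; half-life ln 2/k).

**Validation without data.** A built-in simulator renders
trichrome-like fiber fields with von Mises–distributed orientations of
known concentration κ, so the whole chain is checked against the
ground-truth circular resultant of the sampled angles.

## Worked example

```bash
python examples/simulate_and_analyze.py
```

```
aligned (κ=100)    coefficient=0.942 (ground truth 0.995)  orientation=  59.7°  density=0.472
isotropic (κ=0)    coefficient=0.032 (ground truth 0.039)  orientation= 171.2°  density=0.470
```

Two 512² synthetic fields with 250 fibers each, mean axis 60°: the
strongly concentrated field scores near 1 with the dominant orientation
recovered to within half a degree; the isotropic field scores near 0 (its
"orientation" is meaningless noise). Densities match because both fields
contain the same amount of collagen — alignment and abundance are
independent axes of the readout.

Other narrative examples: `examples/wound_kinetics.py` (decay fit on a
noisy six-day series: k=0.723/day recovered from a true 0.8 at 2% noise),
`examples/group_statistics.py` (paired t-test and Pearson correlation
with months since radiotherapy), `examples/batch_pipeline.py` (manifest →
results table → group statistics).

## Command line

```bash
fibralign simulate --out img.png --truth truth.json --seed 5
fibralign analyze  --in img.png --out result.json
fibralign batch    --manifest manifest.csv --out results.csv
fibralign kinetics --in series.csv --out fits.csv
fibralign compare  --results results.csv --out stats.csv
```

Configuration is TOML (or JSON) with `[preprocess]`, `[alignment]` and
`[kinetics]` tables; every results row carries a hash of the exact
configuration used.

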