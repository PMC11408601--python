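# Methods

## Measurement model

Each pixel of a NanoSIMS acquisition is modeled as a set of independent
Poisson-distributed ion counts, one per detected species, all originating
from the same sputtered nanovolume. Tracer incorporation is expressed through
the isotope ratio R = N/D of a rare-isotope-bearing species over its common
counterpart, and reported as percent above the natural background:

    E = 100 · (R / R₀ − 1)

with default backgrounds R₀(¹⁵N/¹⁴N) = 0.0037, R₀(¹³C¹²C⁻/¹²C₂⁻) = 0.0224
(two ¹³C substitution sites in the carbon dimer; configurable — every
percent-above-background analysis is invariant to this choice), and
R₀(¹²C₂²H⁻/¹²C₂¹H⁻) = 1.56·10⁻⁴ (one hydrogen site, natural D/H). BrdU is a
direct-count ⁸¹Br⁻ channel with no natural background and is used as a raw
count DNA-density proxy. The P/S density proxy has no natural background
either; its reference is the within-image cytoplasmic median, so it is
interpreted ordinally within one acquisition.

Raw ratios are displayed ×10⁴ (0.0037 ↦ 37). Hue-scale (HSI) renderings map
an enrichment interval linearly from blue to red with clamping; rendering
never alters the underlying values.

## Pooled ROI statistics

The primary region statistic is the ratio of summed counts, R = ΣN/ΣD, whose
Poisson standard error is R·√(1/ΣN + 1/ΣD). This is robust at low per-pixel
counts, where single-pixel ratios are unstable. The mean of per-pixel ratios
is reported alongside (pixel-level distributions are themselves an object of
study), and the two coincide for a uniform denominator. Which of the two an
instrument vendor's ROI tool reports is ambiguous in general, so exports
carry both rather than silently picking one.

Per-pixel ratio images mask pixels whose denominator falls below
`min_denominator` (default 20 counts: the single-pixel relative SE is then
already ≈22%, and lower denominators let ratios blow up). The mask, not a
sentinel value, is authoritative; every downstream statistic uses valid
pixels only.

## Synthetic scenes and what they emulate

A `SceneSpec` describes one field: a nuclear ellipse with a laminar rim of
configurable width, nucleolar discs (wholly inside the nucleus, enforced), a
cytoplasmic shell, and an interior chromatin-density field composed of a
seeded smooth correlated random field (Gaussian-filtered white noise) plus
hard discs of dense foci, clipped positive and renormalized to mean 1 over
the modulated region. Compartments partition every pixel with priority
nucleolus > lamina > chromatin focus > nucleoplasm > cytoplasm > background.

Each tracer has a per-compartment enrichment multiplier m (expected ratio
R₀·(1+m); m = 1 is 100% above background). DNA tracers are additionally
modulated by the chromatin-density field; ³¹P scales with density and ³²S
inversely (clipped to [0.5, 2]), reproducing the P-rich/S-poor chromatin
signature and a positive P/S–density correlation. Default compartment
multipliers emulate the canonical imaged nucleus: nucleoplasm 1.0 (RNA and
DNA), nucleolus 4.0 RNA / 0.2 DNA, lamina 0.0 RNA / 2.0 DNA, cytoplasm 0.1
RNA / 0 DNA.

For regression studies, `rna_dna_slope` couples the expected nucleoplasmic
RNA enrichment linearly to the realized DNA enrichment field,
E_RNA = E_base + β·(E_DNA − mean), making β an exact ground-truth slope.
Coupling that would drive expected enrichment negative is rejected rather
than clipped (clipping would silently bend the true slope).

Count budgets are expected denominator counts per pixel inside the cell
(5% of budget outside, emulating resin background). Defaults: 500/px for
¹²C¹⁴N⁻ (pooled nuclear enrichment relative SE < 2% for a typical nucleus)
and 5000/px for the majority-species ¹²C₂⁻ dimer. Budgets are free
parameters of an acquisition (dwell time); recovery studies use:

- nucleolar fold recovery: 200 CN counts/px (a deliberately short-dwell
  condition; the 4× fold is still recovered within 3 SE),
- slope recovery: 5000 CN and 10⁵ C₂ counts/px with density-field SD 0.5.
  At these settings the DNA-enrichment measurement noise (≈3% SD) is
  negligible against the biological spread (≈50% SD), so the
  errors-in-variables attenuation of the OLS slope (factor
  σ²ₓ/(σ²ₓ+σ²ᵤ) ≈ 0.997) is far below the slope's sampling error, and the
  nominal 95% CI covers the true β at its nominal rate. This was chosen from
  counting-statistics arithmetic, not fitted.
- laminar-area and interval-coverage studies: 5000 and 50 CN counts/px
  respectively, with image sizes 64×64 and 32×32 px at 100 nm/px.

Ground truth carries the exact expected counts and expected enrichment per
ratio tracer; by construction the enrichment transform applied to expected
counts reproduces the expected enrichment exactly (simulator/analyzer
closure), which the tests verify to 10⁻⁹ relative tolerance.

What the generator does **not** emulate: detector dead time and
quasi-simultaneous-arrival effects, isotope fractionation, sputtering depth
profiles and 3D structure, realistic mass interferences, cell-to-cell
morphological variation beyond the parameterized geometry, and spatial
correlation of biological noise beyond the smooth density field. Passing
recovery tests therefore demonstrates correctness of the estimators under
Poisson counting statistics and known geometry — not robustness to every
instrumental artifact of real acquisitions.

## Segmentation and compartment metrics

Nucleus segmentation thresholds a lightly smoothed structural channel (³¹P
by default; CN or ³²S selectable) with Otsu's bimodal split, fills holes and
keeps the largest component ≥ 50 px (all components, for multi-nucleus
fields). Being data-relative, it is invariant to positive rescaling of the
channel. On sulfur the brightest region is typically the whole cell; the
cell-minus-nucleus difference yields the cytoplasm.

Putative nucleoli are connected components whose (smoothed) RNA enrichment
exceeds 2× the mean nuclear enrichment with equivalent diameter in the
1–3 μm nucleolar range; their union is the exclusion mask for non-nucleolar
analyses.

The laminar silencing metric emulates label-guided manual border tracing by
thresholding each tracer's enrichment image at a fixed level (default 30%
above background) after mask-aware Gaussian smoothing (σ = 1.5 px default),
then applying 100·(A_DNA − A_RNA)/A_DNA. A negative value (RNA border
outside the DNA border) is reported with a warning, never clamped. This
thresholding is a declared, reproducible stand-in for manual tracing, whose
original visibility criterion is not recoverable; the threshold and
smoothing are exposed in the config. Smoothing shifts a blurred step edge
outward by a fraction of σ that depends on the threshold's position on the
plateau, so comparisons against rasterized geometry are most faithful when
both tracers' borders sit at comparable plateau fractions.

Line profiles resample a polyline at 1-px arc-length steps, averaging
valid pixels over a perpendicular width with nearest-pixel lookup.

## Hotspots

Candidate windows are all w×w squares (default 4×4) wholly inside the search
mask and not intersecting the exclusion mask; the score is the pooled ratio
of summed window counts (at uniform denominators this equals the mean pixel
ratio). Ranking ties break toward higher denominator sums (more precisely
measured windows), then row-major origin order — a deterministic total
order. Under the default `disjoint` policy, windows are accepted greedily in
score order, skipping overlaps; `free` permits overlapping windows. Whether
published top-N windows of this kind overlap is ambiguous; disjoint is the
default because overlapping selection returns N near-copies of the single
maximum. The greedy rule *is* the specification of the estimator, and the
test suite checks exact equivalence against brute-force enumeration plus
greedy filtering.

Complementary-label extraction pools the other tracer's counts over exactly
the same window pixels; the nuclear pooled enrichment accompanies the table
as the reference-line value.

## Pixel statistics

- OLS (two-variable) with slope t-test, per nucleus; a constant regressor
  raises a degenerate-design error instead of returning a zero slope; a
  constant response returns slope 0 with R² = 0. Per-cell p-values carry no
  multiple-testing adjustment (family-wise correction is the consumer's
  choice). Pixels are treated as independent; no spatial-autocorrelation
  correction is applied, and slopes on proxy regressors are per proxy unit.
- MAD is raw (no 1.4826 consistency constant): it is used comparatively
  between distributions, where the constant cancels. COV uses the sample
  (n−1) SD and requires a positive mean.
- Top-percentile subsets use the nearest-rank cutoff k = ⌈pct·n/100⌉ with
  ties at the cutoff included, so the subset size is in [k, n].
- Pulse-chase is a time-indexed family of scenes (per-timepoint
  multipliers), not a kinetic model — the summaries are per-timepoint means.
  Condition contrasts report means, t-based CIs and percent change versus a
  reference; inferential ANOVA/post-hoc machinery is deliberately delegated
  to standard external routines operating on the exported tables.

## Numerical and design choices

- Sampling iterates species in sorted name order from one seeded generator,
  so identical seeds give bit-identical stacks.
- Scene building is deterministic given the spec; texture randomness is
  driven solely by `spec.seed`.
- Ratio grids carry 0.0 at invalid pixels (never NaN/inf); masks govern.
- Window sums use integral images; greedy selection tracks an occupancy
  grid, so detection is O(candidates · log candidates) in the sort.
- Pipeline filenames embed analysis and tracer names, never timestamps;
  manifests list every artifact (including sidecars) with SHA-256 digests.
- Recovery-test problem sizes (64×64 or 32×32 px scenes, 5–500 seeds per
  study) are chosen so the whole suite exercises every estimator's sampling
  distribution while remaining a desk-scale computation.

## Known limitations

- The ¹³C and ²H natural background ratios for dimer species are
  package-chosen defaults (combinatorial arguments), not measured constants;
  absolute-ratio outputs for those tracers depend on them, while
  percent-above-background contrasts do not.
- The Otsu-based nucleus segmentation assumes a single dominant bimodal
  split; dim nuclei over bright debris, or touching nuclei beyond the
  multi-instance variant, are out of scope.
- The laminar metric's agreement with manual tracing on real data is
  unvalidated by construction (no manual traces exist in a synthetic
  scene).
- Hotspot detection is pixel-aligned and square-window only; no sub-pixel
  localization.
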