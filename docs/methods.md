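# Methods

## The measurement model

A whole-cell transmission FTIR spectrum is an absorbance trace on a
wavenumber grid (cm⁻¹). Files may store the grid in instrument order
(descending); internally the grid is always ascending, with absorbance kept
paired on reversal, so interval bookkeeping like "keep [600, 1,800]" has one
sign convention. Two grids count as identical when every point agrees within
1e-6 cm⁻¹ (text round-tripping of floats). The default synthetic/export grid
is 4,000→400 cm⁻¹ at 2 cm⁻¹ spacing (1,801 points): instruments in this
application state a 4 cm⁻¹ optical resolution, which with zero-filling is
conventionally digitized at 2 cm⁻¹; the true digitization spacing of any
particular instrument is configurable, not assumed.

## Preprocessing chain

Order: SNR quality gate → rubberband baseline → vector normalization. Range
selection is deferred to the analysis stage so normalization acts on the
whole recorded spectrum. Whether instrument software applies its quality
test before or after normalization is not public; the chosen order is a
design decision, and `normalization_scope="analysis_range"` exists for
sensitivity analysis.

**SNR gate.** Instrument vendors do not publish their quality-test formula,
so the estimator is operational: signal = maximum baseline-corrected
absorbance in the amide-I window (1,600–1,700 cm⁻¹); noise = RMS of first
differences in the absorption-silent window (default 2,100–1,900 cm⁻¹)
divided by √2 (for white noise, Var(xᵢ₊₁ − xᵢ) = 2σ², and differencing
removes slowly varying residual baseline). The threshold keeps the
conventional value 4,000; both window and threshold are parameters. A
spectrum passes iff SNR > threshold.

**Rubberband baseline.** The lower convex hull of the spectrum restricted to
`n_anchor` (default 64) equally spaced candidate wavenumbers, endpoints
always included, interpolated piecewise-linearly and subtracted. "64 points"
is interpreted as the hull-candidate count, the standard definition of the
named method; the exact proprietary implementation may differ. Guarantees:
output is exactly 0 at hull contact points, ≥ 0 at every candidate anchor,
and invariant to adding any linear function of wavenumber to the input.
Spectra shorter than `n_anchor` fall back to using all points, with a
warning.

**Vector normalization.** Scale so the Euclidean norm over the scoped range
is 1; out-of-scope points are scaled by the same factor. This removes
pathlength/biomass intensity differences: normalize(c·x) = normalize(x) for
c > 0, and the operation is idempotent. All-zero scoped ranges raise.

**Analysis range.** Multivariate stages use [600, 3,800] cm⁻¹ minus the open
interior of (1,800, 2,800) — the CO₂ band and silent region. Boundary points
(exactly 1,800 or 2,800) are retained; on the default grid this gives
601 + 501 = 1,102 points. Atmospheric CO₂/water-vapor compensation is *not*
implemented — instruments do it upstream — and the excluded window removes
the CO₂ band from analysis anyway.

## Per-wavelength significance analysis

The test is the pooled-variance (Student) two-sample t-test, two-sided,
df = n_A + n_B − 2, run independently at every wavenumber; "Student" is
taken literally, with Welch available as a flag. Groups need ≥ 3 replicates.
Degenerate wavenumbers (zero pooled variance) get p = 1 when the group means
are equal and p = 0 otherwise, making constant synthetic fixtures
deterministic.

Binarization is strict: significant ⇔ p < α (default 0.01); p = α maps
to 0, the conservative completion of a threshold stated as "1 for p < 0.01,
0 for p > 0.01".

The optional moving average (default window 10 grid points; 1 = off) smooths
the *absorbance traces* before testing, not the p-value track — a window
"covering 10 wave numbers" most naturally modifies the compared signal; the
p-track reading would be a post-hoc filter. Edges use the truncated
available window, so windows wider than the spectrum degrade gracefully to
the full-spectrum mean (the documented behaviour for short spectra, in
preference to erroring).

Comparison sets: all (n² − n)/2 unordered pairs, or the n − 1 pairs against
a named control; comparisons are ordered lexicographically by condition
label, making outputs deterministic. The percent matrix stores
100 × (significant count)/(total wavenumbers) per tested pair, symmetric
with zero diagonal, full precision internally (rounding only at display);
untested cells in control mode are NaN. The "average number of significant
wave numbers" per pair is implemented as this count/total ratio — no
replicate resampling is involved.

No multiple-testing correction by default: the output is the spatial
pattern of per-wavelength decisions, whose false positives are a known,
uniform α background, not a single hypothesis. `correction="bh"` applies
Benjamini–Hochberg per comparison for users who want it.

`persistent_significant` is the element-wise AND across binary vectors
(e.g. across timepoints), returning the mask and its count.

## Regions and band assignments

The five conventional microbial-IR windows are W1 fatty acids
[2,800–3,000], W2 amides [1,500–1,800], W3 mixed [1,200–1,500], W4
polysaccharides [900–1,200], W5 typing [600–900] cm⁻¹. Published tables
name the windows without printing boundaries; these canonical limits are a
documented convention and fully overridable via CSV. Adjacent windows share
a boundary wavenumber; a shared boundary belongs to the window it *closes*
(1,500 → W3), matching how the band tables place the 1,500–1,483
carboxylate band in the mixed region. W4 is included for completeness.
`region_summary` partitions a binary vector's counts over the windows plus
an "unassigned" bucket (conservation: the row sums reproduce the totals).
The band table carries 16 functional-group ranges across the glycerol and
glucose experiment blocks; lookups return every band containing a
wavenumber.

## PCA

Covariance PCA (mean-centering only — all points share the absorbance unit,
so no per-wavenumber scaling), computed by SVD on the analysis-range matrix,
keeping min(samples − 1, wavenumbers) components. `explained_pct` are the
sample-covariance eigenvalues normalized to 100. Each loading vector is
oriented so its largest-magnitude element is positive — an arbitrary but
deterministic convention that makes score plots reproducible across
linear-algebra backends. Identical input spectra (zero total variance)
raise rather than return an arbitrary basis.

## Viability and yield

M = (1 − Cv/Ct) × 100 with Ct > 0. Values outside [0, 100] are returned
*unclamped* with a warning: serial-dilution counts can legitimately exceed
the control, and clamping would hide it. Dilution series reduce by plain
mean of count × dilution factor over (triplicate) plates; no outlier rule is
applied because none is standard for this assay. Yield percentages divide
ethanol (g/L) by 0.51 × consumed glucose equivalents (g/L); cellobiose
converts at 360.3/342.3 ≈ 1.0526 (one water per hydrolyzed bond). Note the
field habit of calling 2.05% cellobiose "equivalent" to 2.0% glucose does
not match this factor exactly; the stoichiometric constant is used.

## Synthetic data generator

One replicate spectrum is

    absorbance = gain · (Σ Gaussian peaks + condition effects) + baseline + ε

with gain ~ 1 + N(0, gain_sd) per replicate, ε iid N(0, noise_sd) per point,
baseline a low-order polynomial in the scaled coordinate plus one broad
Gaussian hump (σ = 800 cm⁻¹ at 2,000 cm⁻¹), and effects additive offsets on
closed wavenumber bands per condition. Design choices:

- **Gaussian line shapes** (not Lorentzian/Voigt): adequate for exercising
  the statistics, and the analytic mean spectrum stays closed-form for
  Monte-Carlo tests.
- **Multiplicative gain** specifically exercises vector normalization's
  scale invariance; **polynomial + hump baseline** exercises the rubberband.
- **Seed streams** derive per-spectrum RNGs from (seed, condition index,
  replicate index) via `SeedSequence(seed, spawn_key=...)`, so adding a
  condition never perturbs existing draws and everything is bit-reproducible
  from one integer.

Defaults state a realistic well-run instrument: 16 peaks covering W1–W5
(amide I at 1,655 cm⁻¹, amplitude 1.0 — the spectrum's reference height;
the amide II shoulder at 1,512 and the 716 cm⁻¹ nucleic-acid marker included
because downstream band tests target those ranges), noise_sd = 2e-4 (SNR
≈ 5,000, comfortably above the 4,000 gate, consistent with 256-scan
averaging), gain_sd = 1 %, 3 replicates per condition. The graded scenario
builds control + k levels with effect k × base_delta on one band (default
the amide II shoulder), an effect-size ladder standing in for an inhibitor
concentration ladder.

What the generator does **not** emulate: Mie scatter, water-vapor lines,
detector drift, correlated (pink) noise, or biologically realistic covariance
between bands. A green test therefore establishes the statistical machinery
— calibration, power, localization, bookkeeping — on idealized spectra, not
robustness to real-instrument artifacts.

## Numerical conventions

- Grid-identity tolerance 1e-6 cm⁻¹; unit-norm postcondition 1e-9.
- p-values clipped to [0, 1] after the t survival-function call.
- Hull arithmetic uses exact cross-product orientation tests on the anchor
  subset; ties (collinear anchors) are dropped from the hull, which does not
  change the interpolant.
- CSV exports of spectra serialize floats with shortest-round-trip `repr`
  and are read back with `float_precision="round_trip"`, so write→read is
  bit-for-bit and identical seeds give byte-identical tabular outputs.

## Known limitations

- The per-wavelength test ignores spatial correlation along the spectrum;
  runs of significant wavenumbers are interpreted visually, not tested as
  clusters (cluster/permutation inference is out of scope by design).
- At α = 0.01 over the 1,102-point analysis range, ~11 false positives per
  comparison are *expected*; narrow true effects (a few grid points) are
  therefore always a minority of flagged points in a single comparison.
  Persistence across repeated comparisons (the AND mask) is the intended
  tool for isolating them: k independent comparisons shrink the false rate
  to αᵏ while leaving high-power true positives nearly intact.
- With n = 3 replicates per group the pooled t-test at α = 0.01 reaches
  ~83 % per-point power at an effect of 5 noise-SD and > 99.9 % at 10
  noise-SD; detection claims below that range need more replicates or
  smoothing.
- JCAMP-DX support is read-only and limited to AFFN `(X++(Y..Y))` blocks;
  vendor binary formats are out of scope.
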