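# Methods

## Signal model and tensor estimation

Each diffusion-weighted measurement is modeled mono-exponentially:
`S_i = S0 · exp(−b_i gᵢᵀ D gᵢ)`, with `D` a symmetric 3×3 tensor in mm²/s,
`b_i` in s/mm², and `gᵢ` a unit direction in the image coordinate frame (no
scanner-frame reorientation is attempted: phantoms and fits share one
frame).  Taking logs yields a linear system in
(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) solved per voxel by ordinary least
squares — the classic log-linear estimator — with optional weighted least
squares (weights = squared predicted signal, one reweighting pass).  For the
built-in 13-measurement scheme and an isotropic tensor, OLS and WLS have
identical asymptotic MD variance, so OLS is the default.

Rows with signal ≤ 0 are dropped per voxel (their log is undefined); a voxel
is masked out when fewer than 7 usable rows remain or the remaining design
is rank-deficient.  Negative eigenvalues from noisy fits are preserved in
the eigensystem for diagnostics and clamped to zero only when Trace(D), MD
and FA maps are derived, which keeps MD ≥ 0 and FA ∈ [0, 1] by
construction.  Eigenvalues are sorted descending; eigenvector sign is fixed
by making each vector's largest-magnitude component positive, so repeated
runs are bit-identical.

### Built-in gradient scheme

One b = 0 frame plus 12 directions at b = 1496 s/mm²: the six permutations
(2,0,1), (0,1,2), (1,2,0), (2,1,0), (0,2,1), (1,0,2) divided by √5, and the
same six with the unit component negated.  The published source for this
scheme is typographically corrupted, so the reconstruction is a documented
best effort and any user table can override it via FSL-style bval/bvec
files (3-row or 3-column layouts are auto-detected and parse identically).

## Phantoms and noise

The default phantom is a 64×64×5 multi-slice slab (up to 128×128 if
desired): a cortical ellipse with mirrored hippocampal subfield bands (CA1,
CA2/3, DG/hilus), striatum on each side, and — in stroke conditions — a
lateral infarct disk.  The ipsilateral hemisphere is x < nx/2 and label
legends carry side-specific names, so hemisphere assignment is explicit
rather than heuristic.  Every region's ground-truth MD, optional FA and
principal direction are recorded alongside the data, and region geometry is
deterministic; overlapping specialized regions raise an error, and each
region must cover at least 20 voxels.

Condition effects (baseline MDs ≈ 2.9–3.2 × 10⁻⁴ mm²/s, the fixed-tissue
scale):

| condition | infarct | ipsilateral CA2/3 |
|---|---|---|
| intact / sham / KO_sham | absent | ×1.0 |
| MCAO | ×1.5 | ×0.90 |
| KO_MCAO | ×1.5 | ×1.0 |

The effect magnitudes are not published numerically, only graphically, so
these defaults are declared assumptions chosen to give detectable but
non-trivial power at study-scale group sizes.

Noise is Rician — `|S + ε₁ + iε₂|` with ε ~ N(0, (S0/SNR)²) — the
physically appropriate model for magnitude MR images (Gaussian available
for debugging); default SNR 30 on the b = 0 signal.  Between-subject
variability multiplies each region's MD by an independent normal factor
with 3% coefficient of variation per subject.  All randomness flows through
`numpy.random.SeedSequence`, with per-subject child seeds, so cohorts are
bit-reproducible and independent of the order in which group counts are
written in a config (conditions are iterated in sorted order).

A consequence worth knowing: with a single b = 0 frame anchoring ln S0, the
per-voxel MD standard deviation at SNR 30 is ≈ 8% of MD (halving as SNR
doubles) for any least-squares weighting — the closed-form covariance of
the design confirms OLS is already efficient here.  Region-level ROI means
average this away (n ≈ 300 voxels per subfield), but single-voxel
inference at a t = 4.025 threshold has modest per-voxel power for a 10% MD
change, so suprathreshold sets mix true CA2/3 voxels with a comparable
number of whole-brain false positives at α = 0.001.

## Group statistics

* `mean_sem`: sample SD with n−1 denominator over √n.
* `student_t`: pooled-variance two-sample t, two-sided, df = nA + nB − 2
  (Welch optional).  Zero pooled variance with unequal means is reported as
  p = 0 with a flag.
* `tukey_hsd`: all pairwise comparisons via the studentized range with
  pooled within-group variance (df = N − k) and the Tukey–Kramer standard
  error for unequal n.  At k = 2 it reduces exactly to the pooled t-test.
* `critical_t` / `voxelwise_t` / `threshold_contrast`: the voxelwise
  contrast is a per-voxel pooled t between cohorts sharing one grid
  (synthetic subjects are co-registered by construction; no
  realignment/normalization step exists).  The default contrast is
  one-sided control > stroke — an MD decrease — matching the convention
  that t = 4.025 is the one-sided P = 0.001 critical value at df = 11.  No
  multiple-comparison correction is applied ("uncorrected"); a Bonferroni
  threshold can be reported on request.  Voxels with zero pooled variance
  are t = 0 when means agree and undefined otherwise.

## IHC area fraction

Fields are single-plane multichannel images (GFAP, Iba1, DAPI) with known
pixel size.  Coverage is `100 · stained pixels / region pixels` after
thresholding; Otsu per channel per field is the default (parameter-free),
with a fixed threshold available for strict reproducibility, and every
applied threshold is recorded.  No background subtraction or illumination
correction is performed.  Fields under 0.28 mm² are excluded from cohort
reports with a logged reason.  Synthetic fields place disk-shaped marker
blobs by a seeded Poisson process (baseline 120 blobs/mm², radius
6 ± 1.5 µm, 1.5 µm pixels, 400×400 fields ≈ 0.36 mm²); wild-type stroke
doubles the density in CA2/3 while the knockout stroke condition stays at
baseline.  Exact rasterized truth coverage accompanies every field; with the
default two-population intensities (background 10 ± 2, blobs 200 ± 10) the
Otsu measurement agrees with truth to well under 0.1 percentage points.

Against real data, note what the generator does **not** emulate: filamentous
astrocyte morphology, uneven illumination, autofluorescence, out-of-focus
light, and marker colocalization.  Passing tests demonstrate correctness of
the measurement definition, not robustness to those effects.

## Behavioral tables

Freezing percentage (0–100, contextual fear test) and a 21-point
neurological score are drawn per subject from normal distributions clipped
to their valid ranges (scores rounded to integers); group means outside the
valid ranges are rejected.  The simulated detection rate of a
1.5-pooled-SD freezing deficit at n = 6 vs 6 matches the noncentral-t
closed form (≈ 0.65 two-sided at α = 0.05), which is what the tests assert.

## Pipeline and reproducibility

`run_study` executes simulate → fit → roi → vbm → ihc → behavior → report
into one directory from a YAML config; each stage is also a CLI subcommand
consuming/producing the same layout, and chaining the subcommands is
byte-identical to `run_study`.  Volumes are uncompressed NIfTI-1 (label
legends in JSON sidecars, gradient tables as bval/bvec), tables are TSV
with a fixed float format, and a manifest records version, seed, full
config, and per-stage status; any stage failure aborts with the stage named
while retaining partial outputs.  Absent ihc/behavior config sections skip
those stages (noted in the manifest).

### Problem sizes used in tests and the acceptance script

Tensor-recovery and rotation checks use 1000 random physical tensors and
100 rotations; noise-consistency uses a 1000-voxel isotropic phantom at
SNR 30/60/120; cohort-level checks use 20 replicates of the 6-vs-7
wild-type design and 20 of the 4-vs-4 knockout design on the default
64×64×5 grid; null calibration uses 10⁵ voxel-tests and 2000 Tukey
simulations; IHC accuracy uses 50 fields.  These sizes make every
stochastic bound sharp enough to be meaningful while keeping a full run in
the minutes range on one CPU.

## Known limitations

* Single-compartment tensor model only — no DKI, multi-tensor or NODDI;
  no eddy-current/motion correction, registration, or smoothing.
* Phantom anatomy is schematic (stacked 2D shapes), not atlas-based; no
  partial-volume or susceptibility effects.
* Voxelwise inference offers only the uncorrected height threshold (plus
  optional Bonferroni) — no cluster-extent or random-field inference.
* ROI summaries operate strictly on the supplied labels; no CSF exclusion
  or atlas registration.
* The daily neuro-score time course is summarized descriptively; no
  repeated-measures or mixed-effects modeling.
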