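# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical conventions, and the limits of what the synthetic
cohort can demonstrate.

## Nutrient estimation

Intake per nutrient is a linear functional of the FFQ: portion size (g)
× amount-category weight (0 / 0.5 / 1 / 1.5) × weekly frequency / 7 ×
per-gram density, summed over food groups; cooking-method items enter as
extra table rows (grams of added oil/sugar/salt per occasion) with an
implicit weight of 1. Estimated salt is the NaCl equivalent of sodium
(salt g = sodium mg × 2.54 / 1000) and both are co-scaled by the
household salt-taste multiplier (lighter ×1.0, equal ×1.15, saltier
×1.3).

Of the 53 nutrient items, 42 are integrated directly from densities; the
remaining 11 are derived: %energy shares use Atwater factors (4 kcal/g
protein and carbohydrate, 9 kcal/g lipid) against the table's own energy
column, since no conversion is prescribed by the design; the grain
%energy and the vegetable/animal-protein ratios come from food-group
class tags; β-carotene equivalent = β + ½α + ½cryptoxanthin, retinol
equivalent = retinol + βeq/12, tocopherol equivalent = α + 0.4β + 0.1γ +
0.01δ (the standard food-table conventions). Seven class ratios are
computed: animal/vegetable/fish oil shares of class-tagged lipid grams,
saturated/mono/poly shares of total fatty acids, and n-6/n-3.

The bundled food-composition table (29 groups, 10 cooking items) is
**synthetic**: macronutrient densities are plausible per-100 g values
and micronutrients are generated once from a fixed seed with
class-targeted boosts (e.g. B12 and vitamin D concentrated in fish,
eggs and dairy; carotenes in green-yellow vegetables). Licensed national
composition tables cannot be redistributed; a user table in the same CSV
schema drops in unchanged.

Eating behavior is scored as plain sums: 7 category sums over 55 items
on a 1–4 scale. The published item→category assignment is not available,
so the default map splits the items 8/8/8/8/8/8/7 and is configurable.
Missing items are rejected, never imputed.

Body indices: BMI = w/h², fat % = 100·fat/w, FFMI = fat-free mass/h²,
FMI = fat mass/h². Because fat + fat-free mass = weight is enforced at
construction, FFMI + FMI = BMI holds to floating precision.

## Morphometrics

**Pose.** The canonical frame puts the nasion at the origin; the
sagittal plane is the least-squares symmetry plane of the exo- and
endocanthions (x-axis = mean of the two left→right unit vectors); the
axial plane is the least-squares plane through exocanthions, porions and
subnasale, its normal orthogonalized against the x-axis; signs are fixed
anatomically (nasion superior to subnasale, frame right-handed). The
construction is equivariant, hence invariant to rigid motion of the
input and idempotent.

**GPA.** Full Procrustes: every configuration is centered and scaled to
unit centroid size (CS = Frobenius norm of the centered configuration),
because size is analyzed separately through CS. Rotations come from the
SVD solution with the determinant forced positive — anatomical data must
never be mirrored; a configuration whose unconstrained optimum would be
a reflection triggers a warning (planar configurations, where the flip
is fit-neutral, do not). The consensus is re-estimated until its RMS
change falls below 1e-10 or 100 iterations, whichever first.

**Shape PCA and retention.** Eigendecomposition of the covariance matrix
for shape coordinates (their common scale is meaningful) and of the
correlation matrix for nutrient profiles (heterogeneous units). The
literal Kaiser rule (eigenvalue > 1) only makes sense for standardized
variables, so covariance mode uses eigenvalue > mean eigenvalue as the
scale-free analogue. Retained k = min(Kaiser count, smallest k reaching
90% cumulative share): the Kaiser set is kept unless it already explains
more than 90%, in which case it is trimmed to the 90% point. At least
one component is always retained.

**Inter-landmark panel.** The printed 17-variable list contains a
duplicate (|Gla-Ls|/|Zy-Zy| appears twice), so 16 unique variables are
implemented: 12 distances normalized by the exocanthion distance
(|Ac-Ac|, |Zy-Zy|, |Ch-Ch|, |Go-Go|, |N-En|, |N-Sn|, |N-Zy|, |N-Prn|,
|N-Ls|, |Sto-Gn|, |Ls-Li|, |Ps-Pi|) and 4 ratios (|Go-Go|/|Zy-Zy|,
|Gla-Sn|/|Sn-Gn|, |N-Gn|/|Zy-Zy|, |Gla-Ls|/|Zy-Zy|). Midline-to-side
distances and eye height are averaged over the two sides. This
unique-16 reading is a documented interpretation, not asserted as the
original intent.

**Accentuation.** Group mean faces are exaggerated as grand + w·(group −
grand), default w = 5, for visual comparison only.

## Sexual shape dimorphism

SShD(F⃗ᵢ) = ((F⃗ᵢ − midpoint)·F⃗₍m−f₎)/|F⃗₍m−f₎|², where F⃗₍m−f₎ is the
male-minus-female reference mean difference. Centering at the reference
midpoint is a convention choice (the projection formula leaves the
origin unstated); it makes the two reference means score symmetrically
at ±0.5 and is used throughout. Scores below −1 / above +1 are reported
as hyper-feminine / hyper-masculine descriptively; no classification
decisions rest on those thresholds.

The decomposition regresses the aligned shape vectors on CS
(multivariate OLS, one shared slope vector): the allometric score is the
projection of the size-predicted shape deviation b·(CSᵢ − C̄S), the
non-allometric score is the projection of the remainder, and additivity
is exact by linearity of the projection.

Projection requires shapes and axis in one orientation frame:
pose-normalize configurations before GPA so the consensus stays in the
canonical frame the reference means are expressed in.

## Inference layer

- **Stepwise**: forward-only with partial-F entry at p < 0.05 and no
  removal step (the design states only an inclusion criterion; a
  bidirectional variant was considered and rejected as unspecified).
  Candidates collinear with the current model are skipped with a log
  message.
- **MANCOVA**: responses = the stepwise-significant nutrition/behavior/
  body variables, predictors = the union of selected sPCs; Wilks' λ =
  det(E)/det(T) with Rao's F approximation; partial η² = 1 − λ^(1/s),
  s = min(p, q). Per-predictor single-root tests drop one predictor at a
  time. A zero-residual fit returns the λ → 0 limit rather than an
  error.
- **Canonical variates**: whitened cross-covariance SVD; rank-deficient
  sides are reduced to their principal subspace with a log message;
  roots are tested sequentially with Wilks' λ over the remaining roots
  (the joint-vs-sequential choice is unstated in the design; sequential
  is implemented). The first face axis is reconstructable as a shape
  vector through the sPC basis.
- **Clustering**: inputs are the nPC scores plus the 7 behavior category
  sums, each z-scored; for each candidate k the best of 25 seeded Lloyd
  restarts is kept, and k maximizes the second difference of the WSS
  curve (the sharpest bend), evaluated at interior candidates, ties
  toward smaller k. Codes are 1-based.
- **ANOVA/Tukey–Kramer**: one-way ANOVA with η² = SS_between/SS_total;
  pairwise q statistics use the Kramer standard error for unequal n and
  p-values from the studentized range distribution.
- **Benjamini–Hochberg**: standard step-up, monotone, capped at 1,
  original order restored.

## Synthetic cohort: what it emulates, and what it does not

Defaults are the study conditions: n = 115 women in three dietary
patterns with proportions 42/41/32, landmark templates of 60 points (26
named anatomical landmarks + surface semi-landmarks; denser templates
are supported — the full ~6000-point density is not required for
correctness and keeps the test suite fast).

- **Dietary patterns.** Per-pattern mean weekly frequencies are a base
  profile times pattern multipliers (balanced: fish/vegetables up,
  sweets down; high-calorie: meat/fats/dairy up; imbalanced: animal
  protein sharply down, sugar and vegetable oil up). Subject frequencies
  are gamma with shape 50 (≈14% CV about the pattern mean — within-
  pattern variation, not total inter-person variation); amount
  categories are drawn with mean weight 1, so pattern mean intakes equal
  the planted means in expectation. When custom planted mean intakes are
  supplied, frequencies are recovered by weighted non-negative least
  squares — inverting the intake formula — so nutrition estimation is
  exercised end to end. Pattern contrasts were sized so the three
  pattern centroids in the standardized clustering-feature space are
  mutually at least ~5 within-cluster SDs apart, the separability regime
  the clustering stage is designed for.
- **Behavior.** Latent item means shift by pattern (balanced lowest on
  every scale; high-calorie elevated on appetite-related scales;
  imbalanced elevated on external eating, preference and regularity),
  discretized to 1–4.
- **Body coupling.** Fat mass is raised in both unhealthy patterns and
  fat-free mass lowered in the imbalanced one (its sarcopenic-obesity
  signature); means target the reported cohort averages (~51 kg,
  BMI ≈ 20).
- **Faces.** Each face is CS·(T̂ + sᵢ·û + Σ zₘ σₘ m̂ₘ) + ε, where T̂ is
  the unit-size template, û a fixed unit "masculinization" axis (wider
  jaw/zygomata, longer lower face, prominent brow) orthogonalized
  against the similarity group so it is pure shape, m̂ₘ are eight fixed
  orthonormal population modes (also orthogonal to û), and ε is
  isotropic Gaussian landmark noise (0.5 mm default — no error model is
  prescribed, so the simplest Procrustes-compatible choice is used). The
  mode spectrum (σₘ ≈ 0.012 … 0.005 shape units) decays so that a
  handful of components carries ~70% of shape variance, the qualitative
  eigen-structure real facial samples show. The planted displacement
  sᵢ = pattern shift + slope·(CSᵢ − C̄S) holds the dimorphism contrast
  (default 0 / −5·10⁻⁴ / +5·10⁻⁴, sized to an ANOVA η² near 0.1, the
  reported effect-size class) and the allometry (10⁻⁴ shape units per mm
  of CS). CS varies 4% about the template size, independently of
  pattern, so size-related contrasts are null by construction. A random
  rigid motion per subject exercises the alignment stages.
- **Reference axis.** Male/female reference means are T̂ ± ½·sep·û
  (default separation 1), standing in for an external two-sex reference
  sample.

One integer seed feeds independent sub-streams (cluster labels, FFQ,
behavior, body, shape, size), so adding a stream never perturbs the
others and identical specs reproduce bit-identical cohorts.

**What passing tests do not show.** The generator plants exactly the
structure the analysis assumes: linear allometry, a single dimorphism
axis shared by allometry and the pattern shifts, isotropic noise,
Gaussian modes, and cleanly separated patterns. Real cohorts have
correlated landmark noise, nonlinear allometry, overlapping diets,
under-reported FFQs and covariance between shape modes and nutrition
that the generator deliberately omits (mimicking a real covariance
structure is out of scope). Recovery of planted parameters therefore
validates the estimators and the pipeline plumbing, not effect sizes in
any human population, and the published cohort's numeric results are not
reproducible here because those data are not deposited.

## Numerical choices

- GPA tolerance 1e-10 (RMS consensus change), max 100 iterations.
- PCA eigenvalues clipped at 0; tiny negatives from symmetric
  eigendecomposition are numerical noise.
- Ratio fields define 0/0 = 0 (zero intake gives zero ratios).
- Elbow ties break toward smaller k; k-means restarts are seeded per
  candidate k for determinism.
- Problem sizes in the validation suite: planted-parameter recovery at
  n = 200, cluster recovery at the default n = 115, detection power via
  400 Monte-Carlo cohorts, null calibration via 1000-replicate
  simulations, panel null via 200 cohorts of n = 45 — sizes chosen to
  make Monte-Carlo error small relative to the margins being asserted.

## Known limitations

- No semi-landmark sliding and no surface registration: configurations
  must arrive in point-to-point correspondence.
- No energy adjustment, under-reporting correction or dietary-recall
  validation on the FFQ side.
- Train/apply separation is out of scope: all standardizations are
  computed on the analysis sample itself.
- The MANCOVA response/covariate split follows the single reported
  overall-model design; other splits are possible and not explored.
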