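# Methods

This note documents the statistical model, the numerical and design
choices behind it, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Structural covariance model

Structural covariance mapping treats the cross-subject correlation of GM
density between a seed region and every other voxel as the signature of a
shared developmental/structural network. The implementation follows the
standard SPM-style *condition-by-covariate* interaction design for a
two-group cohort:

* columns: per-group intercepts `I_A, I_B`; per-group slopes
  `s·I_A, s·I_B` for the covariate of interest `s`; shared nuisance
  columns (TBV, optionally age);
* `s` and all nuisance columns are mean-centered over the **full sample**
  (not per group), so the intercepts are interpretable and the
  between-group contrast is a pure slope difference;
* a within-group covariance map is the one-sided positive contrast on
  that group's slope — covariance networks are defined by *positive*
  coupling with the seed;
* between-group maps are the two one-sided interaction contrasts
  (`A>B` and `B>A`), reported separately.

Estimation is plain per-voxel OLS with homoscedastic voxel-wise variance
and `df = n − rank(X)`. Subjects are independent draws, so no whitening
or autocorrelation model applies. Whether the original SPM formulation
pooled variance differently is not documented anywhere we know of; pooled
per-voxel residual variance is the natural OLS choice and is what the
permutation inference assumes.

Numerical details:

* design columns are internally rescaled to unit norm before solving
  (t statistics are invariant; this keeps `XᵀX` well conditioned when a
  TBV column in mm³ sits next to unit indicator columns);
* the pseudoinverse (SVD) is used rather than explicit inversion;
* voxels with zero residual variance and nonzero effect are reported at a
  t-cap of 1e6 (and all t values are clipped to ±1e6), preserving ranking
  without infinities — in real data the seed's own voxels produce very
  large but finite t because of measurement noise;
* p values are clipped below at the smallest positive float so they lie
  in (0, 1].

Seed means are extracted from the **smoothed** maps (the same space in
which the statistics run). The seed ROI is a sphere of voxels whose
centers lie within the radius (inclusive, with a ~1e-9 float tolerance so
lattice points exactly on the boundary are kept).

## Family-wise error by permutation max-T

The classical SPM formulation of this analysis thresholds maps with
random-field-theory FWE.
This package instead uses the permutation distribution of the maximum
statistic, for three reasons: it is exact under exchangeability of
subjects, it requires no smoothness estimation or Gaussianity of the
field, and its guarantees are directly testable on synthetic cohorts.
This is a deliberate methodological substitution, documented here; at
matched nominal levels the two approaches select similar voxel sets, but
corrected p values are not numerically comparable.

Scheme (Freedman–Lane): the columns carrying nonzero contrast weight are
the effect of interest; the data are residualized on the remaining
columns, residuals are permuted across all subjects (one exchangeability
block), the full model is refit, and the maximum oriented statistic over
the analysis mask is recorded per permutation. Then

```
p_FWE(v) = (1 + #{b : maxT_b ≥ t_v}) / (B + 1)
```

so the smallest attainable p with B permutations is `1/(B+1)`; B must be
chosen with the target alpha in mind (B = 500 supports alpha = 0.01).
Runs are bit-reproducible for a fixed `rng_seed`; the pipeline derives
per-analysis child seeds from one root `numpy.random.SeedSequence`.

Uncorrected p values are parametric Student-t. For every contrast the
max-null dominates the pointwise null, so `p_FWE ≥ p_unc` holds in
practice (asserted in tests on real runs); it is not enforced by fiat.

## Preprocessing

* **Smoothing**: separable Gaussian, `sigma = FWHM/√(8 ln 2)` converted
  per axis to voxels; default FWHM 12 mm (the conventional level for
  covariance mapping). Boundary handling is zero padding — GM density is
  zero outside the head — with no edge renormalization; a constant field
  is therefore attenuated only in a boundary shell, and an interior
  impulse conserves mass to 1e-6.
* **Analysis mask**: voxels whose across-subject mean smoothed GM exceeds
  0.1 (the conventional VBM implicit-mask level; configurable).
* **TBV**: if the subject table supplies `tbv` it is used as-is; missing
  entries are computed from the subject's own modulated GM map as
  intensity sum × voxel volume. Whether a study's TBV covariate included
  WM/CSF compartments is typically unreported, so the supplied value
  always takes precedence.

## Thresholding, masking, clusters

* Within-group maps: p_FWE ≤ 0.01 (default).
* The "network global map" is the **union** of the two groups' FWE maps
  (a conjunction option exists; the union is the inclusive reading and
  the default).
* Between-group maps: parametric p_unc ≤ 0.05 intersected with the
  global map — by construction a subset of it.
* Clusters: connected components at 26-connectivity by default (6 and 18
  available; 18 mirrors SPM's surface-connectivity convention). The peak
  is the maximal-t voxel, ties broken by smallest C-order linear index;
  up to 3 subsidiary peaks at least 8 mm apart are reported (the common
  reporting default). Atlas labeling takes an integer-labeled volume on
  the same grid: primary label at the peak (0 → "unlabeled"), secondary
  labels by descending cluster overlap.
* Network extent is the suprathreshold voxel count per group; group
  comparisons report the count ratio.

## Synthetic cohorts

The generator plants the minimal statistical structure the analysis
assumes: a single latent factor per subject (rank-1 covariance) loading
on group-specific sets of spherical nodes inside a smooth ellipsoid
phantom (semi-axes 60×75×60 mm on a 40×48×40 grid at 4 mm, world origin
centered). Per subject:

```
y(v) = baseline(v) + loading_g(v)·z + tbv_effect·(TBV − mean)·support(v) + eps(v)
```

with `z ~ N(0,1)`, TBV ~ N(1.25e6, 1.1e5) mm³ (childhood/adolescent
scale), `tbv_effect = 2e-7` density units per mm³ (≈0.02 density units
per TBV s.d.), and noise smoothed to 8 mm FWHM then rescaled so its
interior per-voxel s.d. equals `noise_sd` (the rescaling factor is the
exact ℓ₂ norm of the discrete truncated kernel, so the calibration is
exact, not approximate). A behavioral score emulating a social-impairment
instrument total is `a_g + b·z + noise` floored at 0, with per-group
intercepts (clinical-like group 9.5, control-like 0.7), slope 2.0 and
noise s.d. 1.0 — the floor censors low scores in the control-like group,
as real instrument totals do.

Node geometry: centers are published network-peak coordinates scaled by
0.75 so spheres sit inside the phantom. **Full-network nodes have a 12 mm
radius and the seed anchor 8 mm** — nodes must be at least kernel-sized
(12 mm FWHM smoothing) to be recoverable at all, exactly as real
covariance networks span whole gyri; structures much smaller than the
kernel are attenuated below any sensible threshold, which is a property
of the analysis, not a bug of the generator. The analysis seed is the
conventional small 4 mm sphere at the anchor's center, sampling the core
of a larger planted structure.

Scenarios (`make_scenario`):

* `restricted_sn` — group A carries a five-node anterior network; group
  B only the seed anchor plus a residual 4 mm contralateral node. Planted
  B ⊂ planted A. Defaults: loading 0.15, noise s.d. 0.08, n = 40/group.
* `posteriorized_dmn` — group B loses the anterior node and gains two
  posterior nodes relative to A (both set differences non-empty).
* `null` — identical seed-only networks and a score with zero loading:
  any off-seed or score-covariance detection is a false positive.

What the generator does **not** emulate: cortical anatomy and folding,
registration/segmentation error, multi-factor covariance structure,
age-dependent topology, site/scanner effects, and non-Gaussian score
distributions beyond the zero floor. Passing tests therefore demonstrate
the statistical machinery's correctness and calibration under the model's
assumptions — not robustness to real-data artifacts.

## Validation design and problem sizes

The test suite validates, on cohorts generated at run time:

* exact agreement (1e-8) of betas/t/p with independent per-voxel OLS
  oracles (statsmodels in tests, explicit normal equations in the
  acceptance script) on 100 random small problems;
* empirical FWER within the exact binomial 95% band around the nominal
  0.05 over 100 null cohorts (12 subjects/group, 200 permutations each —
  the score covariate is used for calibration because a *seed* covariate
  is computed from the data itself, so seed voxels are never null);
* ≥90% recovery of planted full-network voxels and a restricted/full
  extent ratio below 0.3 in `restricted_sn` at its defaults
  (40/group, 500 permutations, alpha 0.01 FWE);
* ≥80% sensitivity of the masked between-group map to a planted slope
  difference of 0.2 vs 0.0, plus the exact subset property;
* geometry oracles (257-voxel sphere by lattice enumeration,
  corner-connectivity behavior, kernel mass);
* bit-identical p_FWE maps and reports under a fixed seed.

Problem sizes (12/group nulls, 20 null-safety runs at 200 permutations,
one full-scale scenario run per heavy property) were chosen so the whole
suite completes in a few minutes on one CPU while keeping every
statistical check at full strength at its stated scale.

## Limitations

* Permutation FWE replaces random-field FWE; corrected p values are not
  comparable to RFT numbers at the digit level.
* Only two-group designs with a single covariate of interest are
  supported; no robust/heteroscedastic variants; no cluster-extent or
  TFCE inference.
* The default reproduction seeds (frontoinsular and posterior-cingulate
  coordinates in `pipeline.DEFAULT_SEEDS`) are literature-informed
  reconstructions for adult template space, not ground truth; studies on
  pediatric templates adjust seed placement to local anatomical
  landmarks, and users should edit them for their template.
* Display conventions (left–right flipping) are left to the viewer; data
  stay in the affine's frame throughout.
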