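# Methods

## Signal model and fitting

Each voxel's diffusion-weighted signal is modelled as a two-compartment
mixture of hindered tissue water and free water:

    S_i = S0 [ (1 - f) exp(-b_i g_iᵀ D g_i) + f exp(-b_i d_free) ]

with `f ∈ [0, 1]` the free-water signal fraction, `D` a symmetric PSD
tissue tensor with eigenvalues in `[0, d_free]`, and `d_free` fixed at
3.0e-3 mm²/s — the diffusivity of free water at body temperature, the
standard constant of the free-water imaging literature (configurable via
`FitConfig.d_free`).  High-b shells (b > 1000 s/mm²) are excluded before
fitting (`select_shells`) because non-Gaussian diffusion violates the
mono-exponential tensor model.

The fit is voxelwise Gaussian nonlinear least squares
(Levenberg–Marquardt with an analytic Jacobian).  Multi-shell data — four
b-values in the reference protocol — conditions the voxelwise problem, so
no spatial regularization is applied; the regularized single-shell variant
of free-water imaging is deliberately out of scope.  Constraints are
enforced by unconstrained reparameterization:

* tensor: Cholesky factor `D = L Lᵀ` (PSD by construction), optimized in
  units of 1e-3 mm²/s; eigenvalues are clipped into `[0, d_free]` after
  optimization in the rare case the fit overshoots;
* fraction: a scaled logistic `f = 1.1·σ(u) − 0.05`, clipped to `[0, 1]`
  on output.  The scaling lets the optimizer reach the boundary values 0
  and 1 at finite parameter values, where a plain logistic stalls with a
  vanishing gradient;
* `S0`: log-parameterized (positive).

Initialization is deterministic: `S0` from the mean b=0 signal; `f` from
the two-point estimate comparing the mean b=1000 attenuation with an
assumed tissue mean diffusivity (`lambda_init`, default 0.7e-3 mm²/s); the
tensor by linear least squares on the log of the free-water-corrected
attenuation.  No random restarts are used, so repeated fits are
bit-identical.

Degenerate voxels: when tissue diffusivity equals `d_free` (pure CSF), any
split between the compartments produces the same signal.  The fit resolves
this ridge toward `f = 1` (tensor nearly isotropic with MD > 0.95·d_free
and FA < 0.1) and sets a `degenerate` flag.  All-zero or non-finite
signals return `f = NaN` with `converged=False` — missing, never silently
zero.  Non-positive samples are floored at 1e-6 of the S0 estimate before
fitting, with the count logged.

Noise: the least-squares objective assumes Gaussian noise, as is common in
free-water fitting, while magnitude MRI noise is Rician.  At SNR 30 this
leaves a small negative bias in `f` (measured ≈ −0.006 at f = 0.3 in the
test suite).  The per-voxel sampling standard deviation at SNR 30 on the
44-volume scheme is ≈ 0.08 — the Cramér–Rao bound for this design is
0.080 for a tensor with eigenvalues (1.5, 0.4, 0.4)e-3 mm²/s, so the
estimator is close to efficient and tighter recovery at that SNR is not
attainable voxelwise without shrinkage.

## T2 compensation and iFW

The fitted `f` is a *signal* fraction.  With compartmental
mono-exponential relaxation at echo time TE the apparent fraction is

    f_app = f e_f / (f e_f + (1 - f) e_t),   e_x = exp(-TE / T2_x)

which is inverted in closed form (`t2_correct`) to the volume fraction

    f = f_app k / (1 - f_app + f_app k),     k = e_t / e_f.

This inversion is exact (round trip at machine precision), fixes 0 and 1,
is strictly increasing, and reduces the fraction whenever free water has
the longer T2.  Defaults: TE 109 ms (reference protocol), tissue T2 90 ms
(cortical GM at 3T), free-water T2 2000 ms (CSF at 3T); all configurable
and echoed by the CLI.  The plasma contribution is assumed negligible, and
tissue T2 is a single fixed constant — voxelwise relaxometry or joint
relaxation-diffusion fitting is out of scope.

The interstitial free-water map is then

    iFW = max(FW_corrected − CSFv, 0)

computed voxelwise against an externally supplied CSF fractional-volume
map on the same grid (no resampling: registration is an upstream
responsibility, and geometry mismatches are hard errors).  Negative
differences are projected to zero; values are clipped at one so the result
stays a fraction.

## ROI aggregation

iFW (or any scalar map) is averaged over eight cortical lobes (OFC, LPFC,
MPFC, LTC, MTC, SMC, PC, OCC) defined by grouping parcels of an integer
label map through an editable TSV lookup.  The shipped default groups
Desikan-Killiany cortical parcels (FreeSurfer ctx-* labels 1000+/2000+)
into the eight lobes; it is a plausible reconstruction of such a grouping,
clearly not a canonical atlas definition, and users with their own
definitions supply their own TSV.  Averages are simple arithmetic means
over labelled voxels — no CSFv-based voxel exclusion — with missing-coded
(NaN) voxels excluded from both numerator and count, and empty lobes
reported as missing rather than zero.

## Synthetic data

`simulate_voxel` extends the fit's forward model with a third compartment
and per-compartment T2 weighting:

    S_i = S0 [ w_t (1 − F) exp(−b gᵀ D g) + w_f F exp(−b d_free) ],
    F = f_interstitial + f_csf,   w_x = exp(−TE / T2_x)

so the ground-truth iFW of a phantom voxel is `f_interstitial` by
construction, and noiseless end-to-end recovery (fit → T2 compensation →
CSF subtraction) is an identifiability check of the whole pipeline.  Noise
is Rician (Gaussian optional for debugging) with SNR defined on the mean
noiseless b=0 signal; every draw is seeded.  The reference scheme
(`default_scheme`) carries 5/3/6/30 volumes at b = 0/200/500/1000 s/mm²
and TE 109 ms, with directions spread by deterministic
electrostatic-repulsion optimization from a Fibonacci-hemisphere start
(the real gradient table of any given scanner protocol differs; direction
placement does not enter any tested quantity beyond conditioning).
Phantom tensors are mildly anisotropic with MD in 0.5–1.2e-3 mm²/s,
mimicking cortical gray matter.

`simulate_cohort` emulates the data structure entering the longitudinal
model: three groups (HC, CHR-NP, CHR-P) of 96/127/33 subjects by default,
visits at 0/1/2 years, per-subject Gaussian random intercepts
(sd 0.015), residual noise (sd 0.01), group-specific baseline offsets
(0/0.008/0.010) and yearly slopes (0.0005/0.001/0.004), and covariates:
age uniform on 12–35 years, sex Bernoulli(1/2), ICV lognormal around
1.5e6 mm³ with small linear effects.  Magnitudes were chosen once as
plausible cortical-iFW values; only the group sizes, the age range and
the iFW-like scale are anchored to the study design the toolkit targets.
What the generator does *not* emulate: cortical geometry and
partial-volume structure, registration error, motion/eddy artifacts,
scanner drift, informative dropout, and any correlation between
covariates and group.  Passing tests therefore demonstrate correctness of
the estimators and calibration of the tests under the stated generative
model, not robustness to those real-data effects.

## Longitudinal statistics

Per ROI the model is

    value ~ Group + Time + Group×Time + age + sex + ICV,
    random intercept per subject (REML)

with treatment coding and HC as the reference level, so the Group effect
is the baseline (Time = 0) difference and the interaction the difference
in yearly rate of change.  Age and ICV are z-scored internally for
optimizer conditioning (ICV is ~1.5e6 mm³); the group, time and
interaction inferences are invariant to this.  Omnibus tests are Wald F
tests of the two group dummies (or the two interaction terms) with
denominator df = n_obs − k_fixed; the df approximation is documented as
such and exact small-sample df matching (Satterthwaite/Kenward-Roger) is
not claimed.  Pairwise contrasts (CHR-P vs HC, CHR-NP vs HC, CHR-P vs
CHR-NP) are linear contrasts of the fixed effects with p-values adjusted
over the 3-comparison family by the studentized-range (Tukey) method at
the same df.  FDR across the eight ROIs is Benjamini–Hochberg ("FDR"
without qualification is taken to mean BH).

Degenerate fits are flagged, never silent: a rank-deficient design (e.g. a
single timepoint per subject) raises; a collapsed residual variance or
failed optimization (e.g. noise-free data) falls back to the exact OLS
solution with `singular=True`.  Rows with missing values are dropped
listwise with the count logged.

Rates of change are per-subject OLS slopes (subjects with at least two
distinct timepoints; others excluded and logged).  Clinical associations
use tie-corrected Spearman correlation with two-sided p-values (the
two-sided choice is a documented assumption).  Correlations between
independent groups are compared with Fisher's z:

    z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3)).

Calibration (uniform null p-values of the interaction test; >80% power for
a 1.5 residual-sd/year slope difference at 96/127/33 subjects) is verified
by simulation in the test suite with 200 replicates per condition — null
calibration at reduced sizes (30/40/10, two visits) to keep the suite
fast, power at the full design.

## Known limitations

* The T2 compensation assumes a single fixed tissue T2 and zero plasma
  contribution; no voxelwise relaxometry.
* Gaussian least squares on Rician data leaves a small downward bias at
  low SNR; the noise floor is not modelled.
* The default lobe lookup is a reconstruction; ROI means inherit any
  upstream registration error.
* Mixed-model denominator df are approximate (residual df), so very small
  samples will show mild p-value discrepancies against
  Satterthwaite-based software; estimates agree with lme4 REML to ~1e-6
  in the cross-check test.
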