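# Methods

## The lateralization statistic

For each functional network k, lateralization is the normalized difference
of right- and left-hemisphere cortical surface areas,

    NSAR_k = (RH_SA_k − LH_SA_k) / (LH_SA_k + RH_SA_k),

computed from per-vertex network labels on triangulated hemisphere meshes.
Surface area is accumulated with the barycentric rule — each vertex owns
one third of every incident triangle — so vertex areas sum exactly to the
face-area total and network areas partition the mesh (label 0, reserved
for the medial wall / unassigned territory, absorbs the remainder and is
excluded from network statistics). NSAR is hard-bounded in [−1, +1],
invariant to global mesh scaling, and antisymmetric under exchanging the
hemispheres. A network absent from one hemisphere sits at ±1; absent from
both, its NSAR is undefined and propagated as missing, never imputed or
zero-filled. How a boundary vertex's area should be split between adjacent
labels is not uniquely defined; whole-vertex assignment with barycentric
areas was chosen because it makes area conservation exactly testable.

## Covariate adjustment

Each network's NSAR column is regressed (OLS, per network, no shrinkage)
on four covariates: mean-centered age (years), mean-centered mean
framewise displacement (mm), sex (0/1), and handedness (Edinburgh
Handedness Inventory, −100..100, kept on its raw scale). The adjusted
value subtracts each covariate's fitted contribution measured from its
sample mean,

    adjusted = raw − Σ_i β_i (x_i − x̄_i),

which preserves every network's sample mean, leaves a subject sitting at
the covariate means untouched, and is idempotent (refitting on adjusted
values returns coefficients ≈ 0).

## Identifying lateralized networks

With centered covariates, the intercept of the per-network model estimates
the population mean NSAR; its two-sided t test at the Bonferroni-corrected
level α/K (0.05/17 ≈ 0.00294, displayed as 0.003 but compared unrounded)
is the lateralization test. Across multiple datasets a network counts as
reliably lateralized only if it passes in every dataset with one sign.
Same-direction networks are ranked pairwise by stacking their values in
long format (two rows per subject) and regressing on a 0/1 network
indicator plus the covariates. This long format deliberately ignores the
within-subject pairing of the two rows; a paired t test is available as a
cross-check (`paired_check=True`) and agrees in sign. All tests are
two-sided and parametric (t distributions); no permutation inference.

## Reliability

Two-session reliability uses the two-way single-measures intraclass
correlation. The default **consistency** form satisfies, for k = 2
sessions, ICC = (F − 1)/(F + 1) with F = MS_subjects/MS_error on
(n−1, n−1) degrees of freedom and an exact F-based 95% CI; the
**absolute-agreement** form (which additionally penalizes session mean
shifts, with a Satterthwaite CI) is available via `form="absolute"`,
because printed two-session results in this literature are sometimes
consistent with one form and sometimes the other. Data quantity is
treated abstractly: stability curves take per-increment value vectors and
an independent reference, never raw time series. Exact Wilcoxon
signed-rank p-values are computed by counting over all 2^n sign
assignments (collapsed over equal rank sums; zeros dropped, ties averaged)
for n ≤ 25, with a tie- and continuity-corrected normal approximation
above. The n = 8 all-positive case gives V = 36 and two-sided
p = 2/256 ≈ .008.

## The autonomy index

For convergent validity, a connectivity-based specialization measure: per
vertex, the fraction of supra-threshold (r > 0.25 by default) functional
connections to the ipsilateral hemisphere minus the fraction to the
contralateral one, each normalized by hemisphere vertex count; per
network, the mean over the network's vertices in both hemispheres. Because
the dominant hemisphere's vertices dominate that mean, the aggregate
*grows with specialization regardless of side*: across subjects it
correlates negatively with NSAR for left-lateralized networks and
positively for right-lateralized ones — the sign pattern this package
tests. A `sign_flip` flag negates the output for convention alignment with
other tools. The exact thresholding and normalization conventions of
published autonomy-index variants differ; this implementation fixes the
count-based definition above and exposes the threshold.

## Relationships between lateralized networks

The dependent hypothesis — stronger left lateralization of one network
accompanying stronger right lateralization of another — is quantified
three ways: (1) Pearson correlation between per-subject averages of
adjusted NSAR over the left-lateralized and the right-lateralized network
sets; (2) the full network-pair Pearson matrix with t-based p-values and
Fisher-z 95% CIs (the p < .05 display threshold masks rendering only,
never inference); (3) factor models.

Assumption tests: Bartlett sphericity χ² = −(n − 1 − (2p+5)/6)·ln|R| on
p(p−1)/2 df; KMO as Σr²/(Σr² + Σq²) with anti-image partial correlations
q from R⁻¹ (identically 0.5 for p = 2, a useful algebraic fixture); VIF =
1/(1−R²) per variable; and the Doornik–Hansen omnibus normality statistic
(standardize, orthogonalize through the correlation matrix's
eigenstructure, apply the D'Agostino skewness transform and a
gamma-approximation kurtosis transform per component, sum of squares ~
χ²(2p)).

EFA is iterated principal-axis factoring: squared multiple correlations as
initial communalities, eigendecomposition of the reduced matrix,
communalities updated from loadings to tolerance 1e-6 (max 200
iterations), Heywood communalities clipped to 1 with a warning, no
rotation (bipolar unrotated loadings are the object of interest here;
rotation can be applied downstream by the user). Retention combines the
eigenvalue ≥ 1 rule with parallel analysis against the 95th percentile of
reduced-matrix eigenvalues from matched random-normal data, compared
position by position.

CFA is normal-theory maximum likelihood: Σ(θ) = ΛΦΛᵀ + Ψ with simple
structure, factor variances fixed at 1 and the factor covariance fixed at
0 by default, minimizing F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p (L-BFGS-B
with multiple starts; an independent Nelder–Mead search over the same
parameterization agrees to 1e-4 in the tests). T = (n−1)·F_ML with df =
p(p+1)/2 − free parameters (df = 2 for 4 indicators under the fixed-zero
constraint, df = 1 with a free covariance); CFI against the diagonal
independence baseline with the same n−1 convention; RMSEA =
√(max(T−df,0)/(df(n−1))); SRMR over all unique standardized residual
moments including the diagonal. Loadings are reported standardized
(λ/√Σ_jj).

**Identification caveat.** With two indicators per orthogonal factor, the
loadings are identified only up to their within-factor product (one
covariance, two free loadings): df = 2 counts moments, not identifiable
directions, and fitted loadings can wander along the λ_iλ_j = s_ij ridge —
which is also why standardized loadings slightly above 1 can appear in
published fits of this structure. The package reports the fitted point the
optimizer reaches; tests assert only identified quantities (the products,
the discrepancy value, and the fit indices).

## The synthetic-data generator

Real individual parcellations require restricted fMRI datasets, so every
pipeline stage is validated against generated populations with known
ground truth. Subject-level NSAR is

    y_ik = μ_k + (Λ f_i)_k + x_iᵀβ + ε_ik,  ε ~ N(0, σ²), f ~ N(0, Φ),

truncated to [−1, 1] by clipping (warning above 1% truncation). Defaults
(the study conditions; fixed, not tuned per test):

| quantity | default | rationale |
|---|---|---|
| networks | 17 canonical resting-state networks | matches the 17-network scheme |
| planted means | 3 left (−0.15..−0.25), 5 right (+0.10..+0.30), 9 null | the replicated 8-network pattern, magnitudes on the observed NSAR scale |
| loadings Λ | 0.08 on a left factor (left networks) / right factor (right networks) | within-set network correlations ≈ 0.39, the printed correlation scale |
| factor correlation | −0.65 | the headline left/right coupling |
| residual σ | 0.10 | total per-network sd ≈ 0.13 |
| covariate slopes | age 0.001/yr, sex 0.01, FD 0.1/mm, EHI 1e-4 | small, as observed (no covariate was reliably significant) |
| covariates | age ~ N(28.5, 3.6²) in [22, 36]; 40% male; FD ~ N(0.08, 0.02²); EHI 90% right-handed mixture | adult-cohort demographics |
| meshes | icosphere subdivision 4 (2562 vertices/hemisphere), radius 100 mm | exact geometry; area ratios are resolution-independent |
| assigned area | 85% of the surface, equal network fractions | medial-wall stand-in plus feasibility headroom for strongly asymmetric subjects |

With residual attenuation, the model-implied correlation between the
left-set and right-set averages is ≈ −0.46 for factor correlation −0.65;
`implied_average_correlation` reports this generating value and recovery
is judged against it, since attenuation is part of the model, not noise.

Parcellations are rendered by seeded multi-source region growing to
per-hemisphere area targets RH_k = S_k(1+t_k)/2, LH_k = S_k(1−t_k)/2; a
vertex is accepted while overshoot stays under half its own area, so
achieved NSAR sits within about one vertex area of the target (measured
max error ≈ 0.003 at subdivision 4, against a stated ±0.02 tolerance).
Run-level variability reassigns a fraction of label-boundary vertices to
neighboring labels. Connectivity matrices come from a latent-signal block
model (bilateral network signal with weight √(h·r), hemisphere-specific
signal with weight √((1−h)·r)), giving within-hemisphere correlation r and
cross-hemisphere correlation h·r, positive semidefinite by construction
before small symmetric noise; the homotopy weight h moves the autonomy
index monotonically to ≈ 0 at h = 1 for symmetric networks. Connectivity
generation is guarded to ≤ 2000 total vertices — it is a validation
substrate, not a simulator of full-resolution connectomes.

What the generator does *not* emulate: BOLD time series, spatial
autocorrelation of parcellation errors beyond boundary resampling,
site/scanner effects, non-Gaussian NSAR distributions, and any genuine
biological coupling mechanism — passing tests show the estimators recover
the planted statistical structure, not that real cortices obey it.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use: 300 subjects per
cohort (3 cohorts), 100 replicates for planted-network recovery, 2000
replicates for error-calibration (family-wise error under the global
null; Doornik–Hansen size), one full rendered-mesh round trip at n = 300,
and small icospheres (subdivision 2–3) for connectivity and run-splitting
harnesses. These sizes give Monte-Carlo standard errors well inside the
asserted tolerances. Monte-Carlo assertions carry their own binomial
margins rather than relying on a particular seed. Ties in the Hungarian
assignment resolve deterministically (lowest row index first); EFA factor
signs are fixed by making each factor's largest-magnitude loading
positive; dice for a network absent from both parcellations is reported
missing rather than 0 or 1.

## Limitations

- Surface areas use whole-vertex label assignment; sub-vertex boundary
  geometry is not modeled.
- The pairwise network comparison inherits the long-format independence
  assumption described above.
- The two-indicator-per-factor CFA is under-identified in its individual
  loadings (see the caveat); interpret products and fit indices.
- The exact Wilcoxon switches to a corrected normal approximation above
  n = 25.
- Parcel matching pools hemispheres in one assignment; per-hemisphere
  matching, graph-regularized matching, and probabilistic assignment are
  out of scope.
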