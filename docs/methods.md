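# Methods

`scngraph` implements a group-level structural covariance network (SCN)
analysis of regional gray-matter volume (GMV), together with a synthetic
cohort generator that makes every stage of the pipeline testable without
MRI data. This note describes the statistical model behind each stage,
the tunable parameters and their defaults, the design choices made where
the design was genuinely open, and the limits of what the synthetic
experiments demonstrate.

## Pipeline

Input is a cohort table: one row per subject with a group label
(patient / control), clinical covariates — age (years), sex (0/1),
education (years), total intracranial volume (TIV, ml), HAMA and HAMD
scores, PSQI score — and mean GMV (mm³) for each of the 90 cortical and
subcortical regions of the AAL parcellation.

1. **Confound regression.** For each region independently, GMV is
   regressed by ordinary least squares on an intercept plus six
   covariates (HAMA, HAMD, TIV, age, sex, education), and residuals
   ("corrected GMV") replace the volumes. The model is fitted on the
   pooled sample without a group term, so group-related differences
   survive into the residuals while nuisance structure is removed;
   `scope="per-group"` fits within groups instead. Pooled fitting is
   the default because it keeps residual rows exchangeable under the
   null, which the permutation test relies on.
2. **Network construction.** Per group, the 90 × 90 Pearson correlation
   matrix of corrected GMV is computed, negative entries are set to
   zero (edges are positive covariance only), and the matrix is
   binarized at fixed sparsity: the K = ⌊density · R(R−1)/2⌋ strongest
   positive correlations become edges. Both groups therefore carry
   exactly the same edge count at every density. The sweep runs from
   0.10 to 0.50 in steps of 0.02 (21 densities); the lower bound is the
   minimum density at which both groups' networks form a single
   connected component (`min_connected_density` verifies this and
   reports per-density diagnostics). Ties at the K-th rank are broken
   by (row, column) index order — deterministic, and it makes edge sets
   nested across the sweep.
3. **Graph topology.** On each binary network: clustering coefficient
   (Watts–Strogatz nodal mean; nodes with degree < 2 contribute 0),
   characteristic path length (mean BFS distance over reachable pairs;
   unreachable pairs are excluded), global and local efficiency (with
   1/∞ = 0), nodal degree, nodal efficiency, and betweenness centrality
   (Brandes, unnormalized, each unordered pair counted once). The
   small-world triplet normalizes against degree-preserving rewired
   references: gamma = Cp/⟨Cp_rand⟩, lambda = Lp/⟨Lp_rand⟩,
   sigma = gamma/lambda. References are Maslov–Sneppen double-edge-swap
   rewirings, 100 per network with 10 swap attempts per edge, seeded.
   The reference count and attempt budget are this package's
   conventions; the construction is the standard one for "normalized"
   clustering and path length.
4. **Group inference.** Every metric curve is summarized by its
   trapezoidal area under the curve (AUC) over the sweep. Group
   differences of AUCs (patient − control) are tested by label
   permutation: labels are shuffled preserving group sizes and the full
   correlation → threshold → metrics → AUC pipeline is rebuilt per
   shuffle (1000 permutations by default). Two-sided p-values use the
   add-one rule p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1), so the
   smallest attainable p is 1/(n_perm+1). Nodal families (degree,
   nodal efficiency, betweenness) are corrected across the 90 regions
   by Benjamini–Hochberg FDR, each metric family separately; the five
   global metrics are reported uncorrected. Because residualization is
   group-agnostic, it is fitted once before permutation; a
   `repermute_residuals` flag forces refitting per shuffle (it only
   changes anything under per-group residualization).
5. **Hubs.** Betweenness is normalized by the network mean at each
   density, averaged over the sweep as AUC/(d_max − d_min), and a region
   is a hub when its profile strictly exceeds mean + 1 sample SD
   (ddof = 1; both conventions are flags). The density-averaged profile
   is used because the hub definition does not name a density and AUC
   is the pipeline's summary device for everything else. The rule is
   translation- and scale-invariant in the hub set.
6. **ROI morphometry.** Region-level GLMs: a patient-vs-control
   contrast (intercept + group + six covariates) with a t-test on the
   group coefficient, and Cohen's d computed as the covariate-adjusted
   group difference divided by the pooled residual SD (√MSE); and a
   within-patient multiple regression of volume on PSQI with the same
   covariates. These are region-table analogs of a voxelwise analysis
   and are **not** equivalent to voxel-cluster inference: there are no
   clusters, no cluster-extent thresholds, and no family-wise error
   correction — per-region uncorrected p plus a BH-FDR column is
   reported instead.

## Synthetic cohorts

The generator emulates the tabular product of a volumetric morphometry
pipeline under the study conditions: 82 patients vs 73 controls by
default, with patient PSQI ≥ 8, control PSQI ≤ 7, and strongly elevated
patient HAMA/HAMD, covariates drawn independently (age ≈ N(37.5, 11),
TIV ≈ N(1445, 115) ml, clinical scores truncated discretized normals).

Regional volumes are multivariate normal around a 6000 mm³ baseline
with 600 mm³ noise SD. The population correlation matrix blends four
components, chosen to mirror the qualitative anatomy of empirical GMV
covariance:

* a **floor** correlation shared by all pairs (default 0.55 before
  blending) — global morphometric covariance;
* **modules** of three consecutive homotopic pairs (six regions) with
  elevated within-module correlation (0.8) — local structural
  covariance;
* a **homotopic boost** (+0.2) between left/right homologs — the
  mirror-symmetric covariance that dominates empirical association
  matrices;
* a smooth **distance-decaying kernel** (amplitude 0.25, Gaussian in
  chordal distance on a ring of homotopic pairs, scale ≈ 6 pairs) plus a
  fixed **random-factor component** (rank 6, blend weight 0.3, drawn
  once from a structural seed so every cohort shares the same
  "anatomy") — graded pair-level heterogeneity and long-range
  shortcuts.

Two properties of this parameterization matter and drove its
calibration. First, module size: at 10% density only 400 edges exist,
so modules must own fewer pairs than that (15 modules × 15 pairs = 225),
leaving ~175 edges as inter-module bridges — this is what keeps the
thresholded network connected at the bottom of the sweep while the
module cliques and kernel neighborhoods push normalized clustering above
1 everywhere. Coarse modules (whole lobes, ~750 within pairs) would
fragment the 10% network into lobe components. Second, the correlation
level: with ~75 subjects per group the sampling SD of a correlation is
≈ 0.1, and if the bulk of true correlations sits at that scale, edge
ranks near the threshold are noise rather than signal, per-node degree
becomes dominated by node-level sampling effects, and no group
difference of realistic size is detectable after FDR across 90 regions.
Keeping the bulk of the distribution well above the sampling noise
(median ≈ 0.43, graded up to ≈ 0.9) makes edge ranks stable, which is
also what real GMV covariance matrices look like.

Injectable effects, echoed by `ground_truth` for recovery scoring:

* `group_effect` — per-region mean shift in noise-SD units, patients
  only. Visible to morphometry; invisible to the correlation network
  (correlations are location-invariant).
* `group_decoupling` — per-region factor f ∈ [0, 1] scaling the
  patient-group correlations of a region (C′ = D C D + (I − D²) keeps
  the matrix a valid correlation matrix by construction). This is the
  knob that moves network topology.
* `psqi_effect` — within-patient slope of volume on PSQI (SD units per
  point), centred at the patient PSQI mean so it is not an extra group
  shift.

Degenerate inputs: an implied correlation matrix is validated by its
eigenvalues (hard error below −5·10⁻³, or −10⁻⁸ for explicit override
matrices; smaller deficits from the additive boosts are projected onto
the nearest PSD correlation). Volumes are floored at 1% of the baseline
mean because non-positive volumes are anatomically impossible.

### What the synthetic experiments do and do not show

Generated cohorts reproduce the statistical structure the analysis
assumes — modular, homotopically mirrored, graded positive covariance;
covariate confounding; group-separated clinical scores — but not the
features of real morphometry that the model omits: measurement noise
correlated with image quality, non-Gaussian volume distributions,
site/scanner effects, spatially autocorrelated parcellation error, or
any causal link between clinical scores and anatomy. Passing tests
demonstrate that the pipeline is correct and calibrated (type-I error,
effect recovery, determinism) under its own assumptions; they do not
validate any neuroscientific claim about insomnia or any other
condition.

## Numerical and experimental choices

* Edge-count rounding is ⌊·⌋ so achieved density never exceeds the
  target; both groups match exactly.
* Permutation resolution: with the add-one rule, min p = 1/(n_perm+1).
  A single FDR-corrected discovery among 90 regions at q < 0.05 needs
  p ≤ 0.05·rank/90, so recovery experiments use 2000 permutations
  (min p ≈ 5·10⁻⁴ < 0.05/90); the pipeline default stays at 1000,
  where discoveries require two or more regions near the floor —
  exactly the bilateral/multi-region pattern the decoupling experiments
  inject.
* The decoupling recovery experiment perturbs a whole 6-region module
  (factor 0.1) rather than one region: a single region's maximal
  achievable degree deficit sits only ~2.5 null SDs from zero at
  n = 80 + 70, below the FDR bar, while a module-wide perturbation both
  deepens each region's deficit and raises the BH rank.
* The Cohen's d recovery check averages over 5 replicate cohorts at the
  full n = 82 + 73: HAMA/HAMD are strongly group-separated, which
  inflates the variance of the adjusted group contrast (variance
  inflation from near-collinearity of group with the mood covariates),
  so a single-cohort estimate of d has SE ≈ 0.17 and the replicate mean
  controls Monte Carlo error without touching the ±0.25 recovery bound.
* Null-calibration experiments run 200 replicate pipelines at a reduced
  size (30 + 30 subjects, 200 permutations) and the acceptance sweep
  uses 100 rewired references per density; these sizes keep the whole
  suite at desk scale while leaving the binomial check on the 5% level
  well-powered.
* Rewiring that cannot find a single valid double-edge swap (stars,
  complete graphs) raises an error rather than silently returning the
  input.
* Disconnected networks are a guarded edge case, not a normal path: the
  sweep minimum is chosen for connectivity, and `metric_curves` warns
  if a group's network is fragmented at the sweep minimum (at default
  cohort sizes this occurs in roughly 1 in 25 group-networks, and the
  distance conventions above handle it).

## Known limitations

* Group-level networks only: one covariance network per group, no
  individual-level SCNs, no weighted or signed variants, no
  negative-correlation analysis.
* The hub-count and hub-identity outputs depend on the density-averaged
  betweenness profile; other summaries (single density, degree-based
  hubs) would give different hub sets.
* The permutation test assumes exchangeability of residual rows under
  the null, which pooled residualization provides; per-group
  residualization combined with permutation requires refitting per
  shuffle and is slower.
* Sigma inside the permutation loop multiplies rewiring cost by
  n_perm × n_densities and is off by default (`n_refs_perm = 0`);
  global-metric permutation tests cover clustering, path length and
  efficiencies, with sigma tested observationally across the sweep.
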