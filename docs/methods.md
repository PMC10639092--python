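# Methods

This note documents the models and numerical choices behind strokenet:
what the synthetic cohort emulates, how the connectome and its metrics
are defined, how the group statistics are coded, and what passing the
test suite does and does not establish about real data.

## Study design being emulated

A three-group cross-sectional comparison: healthy controls, young
ischaemic-stroke patients without post-stroke epilepsy (noPSE), and
patients with post-stroke epilepsy (PSE). Each subject contributes one
resting-state BOLD run parcellated into 82 grey-matter regions (41 per
hemisphere: 34 cortical regions in Desikan–Killiany naming plus 7
subcortical structures; the cerebellum is excluded), a confound matrix,
demographics (age ≈ N(49, 10²) truncated to 18–70, sex Bernoulli(½)),
lesion descriptors and raw scores on an eight-test neuropsychological
battery covering seven cognitive domains. Default group size is 30 per
group; the reference acquisition is TR = 1.87 s with 200 retained
volumes after 4 dummy volumes.

## Synthetic BOLD model

Each subject's signal is multivariate normal with unit node variance,
`x_t ~ N(0, Σ)`, drawn independently across volumes (a config flag adds
AR(1) smoothing with variance-preserving innovations; default off). No
haemodynamic convolution is applied: every downstream stage consumes
only second-order structure, so temporal realism beyond the band-pass
is irrelevant to what the pipeline measures. White measurement noise
(sd 0.05) is added after the correlated draw. Confounds are synthetic:
six slowly drifting motion traces and two noisier tissue-mean traces,
independent of the neural signal.

The ground-truth correlation matrix Σ is built in four steps:

1. **Block-modular base.** Five bilateral communities (default-mode/hub,
   sensorimotor, visual, association, subcortical); within-module
   r = 0.15, between-module r = 0.02.
2. **Hub elevation.** Every edge incident to a hub region (precuneus,
   posterior cingulate, caudal anterior cingulate, insula, superior
   frontal, supramarginal, inferior parietal — bilaterally) gains
   +0.70, capped at 0.85. Hubs are hubs *because* their couplings are
   strong; this also matters technically — with weak hub edges, a
   planted hub attenuation is almost invisible downstream, because
   proportional thresholding replaces dropped hub edges with the next
   strongest edges and the max-weight normalization of the Onnela
   clustering cancels near-uniform weight changes.
3. **Shared stroke effect.** Both stroke groups have all
   interhemispheric entries multiplied by 0.80, the canonical remote
   effect of a unilateral infarct. Among the mechanisms explored
   (uniform attenuation, between-module attenuation, extra measurement
   noise), this is the one that moves strength, global efficiency,
   local efficiency *and* clustering in the observed direction for
   patients versus controls: it weakens strong cross-hemisphere
   triangles while leaving the within-hemisphere maximum weight — the
   clustering normalizer — untouched. Uniform attenuations are
   scale-invisible to normalized clustering, and added noise *raises*
   it.
4. **Epilepsy-specific hub attenuation.** For a PSE subject, every
   off-diagonal entry incident to a hub node of the hemisphere
   contralateral to the lesion is multiplied by (1 − a), default
   a = 0.3. noPSE subjects receive the same operation at a fraction
   0.05 of a (mild hub involvement without epilepsy). A bilateral
   lesion attenuates both hemispheres; a stroke without a visible
   lesion has no hub effect. Setting a = 0 removes the PSE/noPSE
   difference entirely.

The result is projected to the positive semi-definite cone by
eigenvalue clipping at zero and renormalized to unit diagonal; sampling
uses an eigen-factor so singular matrices are handled exactly.

Lesion sides are drawn with probabilities 0.45/0.45/0.05/0.05
(left/right/bilateral/none) so the regional-analysis exclusion logic is
always exercised; lesion volumes are log-normal with a larger scale in
the PSE group, and anti-epileptic drug use is frequent only there.

**Cognition.** The processing-speed ability of subject *i* is
`a_i = β·z(m_i) + γ·(age_i − 49) + ε_i` with m the contralesional
precuneus clustering AUC (bilateral mean where no single contralesional
hemisphere exists), β = 0.47, γ = −0.02/year, ε ~ N(0, 0.88²) — the
noise scale makes the score variance ≈ 1, so the control-standardized
coefficient is ≈ β. Two tests record it, one positively oriented
(symbol–digit) and one time-scored (Stroop, orientation −1), which
exercises the sign alignment of the Z-scoring step. All other domains
are independent standard normal draws.

## Cleaning

Fixed order: remove the first 4 volumes → demean and linearly detrend →
zero-phase Butterworth band-pass 0.01–0.08 Hz → confound regression.
The filter order is 2 applied forward–backward (effective order 4, zero
phase) with reflective padding of length 3·(2·order+1); zero phase
preserves the lag structure on which correlations depend. The 8 base
confounds are expanded to 32 columns (originals, backward-difference
derivatives with a leading zero, squares, squared derivatives); a ninth
global-signal regressor can be added by passing a 9-column base matrix.
The expanded confounds are passed through the same band-pass before the
least-squares regression, so the regression cannot reintroduce
out-of-band frequencies; the solve is minimum-norm, so rank-deficient
designs degrade gracefully with a logged warning.

## Connectome construction

Correlation → Fisher z → zero negatives → proportional thresholding, in
that order. Thresholding keeps the K = round(d·N(N−1)/2) strongest
edges with their weights (round half up; the networks stay weighted);
ties at the cutoff break by ascending (i, j) node-pair order, which
makes the sweep deterministic and its edge sets nested across
densities. Correlations of zero-variance nodes are set to zero with a
warning; |r| = 1 is clipped to 1 − 10⁻⁷ before artanh. AUC integration
uses the trapezoidal rule on the 8 grid points (a single-density sweep
returns the raw value with a warning).

## Graph measures

All measures are implemented in this package and verified against
brute-force oracles (Floyd–Warshall triple loop, triangle enumeration,
exhaustive path enumeration, exhaustive partition search) and against
networkx in the test suite.

* Edge length for geodesics is 1/w; unreachable pairs contribute zero
  efficiency. `shortest_paths` offers Dijkstra per source and a
  vectorized Floyd–Warshall; both are exact and cross-checked, and the
  efficiency metrics use the Floyd–Warshall route internally for speed.
* Clustering is the Onnela geometric-mean form with weights normalized
  by the matrix maximum; C_i = 0 for degree < 2.
* Local efficiency defaults to the plain variant — the weighted global
  efficiency of the neighbour-induced subgraph — which has a clean
  independent oracle; a cube-root variant (subgraph distances on w^⅓,
  weighted by the centre node's connection strengths) is available via
  `variant="cuberoot"`.
* Betweenness is Brandes' algorithm on weighted lengths, unnormalized,
  halved for undirectedness; the global summary is the node mean.
* Modularity is Newman's weighted Q with resolution γ (default 1)
  optimized by Louvain with 10 seeded restarts; the returned Q is
  recomputed from the final partition by the direct formula, and the
  per-subject restart seed derives from a CRC-32 of the subject id so
  results are reproducible independent of processing order. On graphs
  with ≤ 6 nodes the optimizer matches exhaustive partition search in
  every test case.

Global scalars are node means computed per density *before* AUC
integration; modularity is global-only.

## Group statistics

* **Z-scores**: per test, z = sign·(raw − control mean)/control SD;
  domain scores average the available tests of a domain; impairment is
  z < −1.5. "Age-adjusted" control references are available as decade
  bins (`age_adjust=True`), but the default uses the overall control
  mean and SD, matching the plain form of the standardization formula.
* **Chi-square** on 2×2 impairment tables is Pearson's without
  continuity correction (Yates optional), p from χ²(1).
* **ANCOVA**: OLS of metric on a group indicator (noPSE as reference,
  so the coefficient is the PSE effect), age in years and a male
  indicator; rank-deficient designs raise rather than silently drop.
* **Regional models** run per (region, metric) on the contralesional
  hemisphere: subjects with bilateral lesions or no lesion are excluded
  first (with reconciling bookkeeping), each remaining subject
  contributes the contralesional node's value under the
  hemisphere-free region name, and nodal metrics are computed on the
  whole 82-node network before selection. Model 1 adjusts for age and
  sex; Model 2 additionally for lesion volume. Benjamini–Hochberg
  adjustment (step-up, adjusted p capped at 1) is applied within one
  metric's family of regions.
* **Cognition regression**: domain Z on the standardized regional
  metric, age, sex and AED use, in the PSE group; constant covariates
  are dropped (not every synthetic cohort has AED variation), a
  zero-variance predictor raises, and fewer than 5 subjects flags the
  result rather than failing.

## Problem sizes used in the checks

The validation suite runs the study at its reference size where the
property demands it and at reduced size where it does not: the
group-ordering check pools three seeded 90-subject cohorts at
T = 200; the detection-rate check runs 100 replicate cohorts at full
size but computes only the strength pathway; type-I calibration uses
200 null cohorts of 20 subjects per stroke group at T = 100; oracle
equivalence uses 200 random graphs of up to 10 nodes. These sizes are
the package's own choices for a thorough-but-quick default validation.

## What the synthetic data do and do not establish

The generator reproduces the *second-order* structure the pipeline
consumes — modular correlations, hub dominance, hemispheric asymmetry
of a planted group effect, covariate structure, and a cognition
coupling with realistic effect size. It does not emulate haemodynamic
convolution or autocorrelation (beyond optional AR(1)), head-motion
artifacts coupled to the signal, physiological noise spectra,
between-subject variability of the connectome (all subjects of a group
share one ground-truth Σ), scanner drift, or lesion-dependent signal
dropout. Passing tests therefore demonstrates that the pipeline's
algebra, bookkeeping and inference are correct and that effects of the
planted size are recoverable end to end — not that the pipeline is
robust to every artifact of real resting-state fMRI.

## Known limitations

* The per-subject variance of correlation estimates is dominated by the
  narrow pass-band (≈ 50 effective samples at T = 200, TR = 1.87 s);
  group effects smaller than roughly a third of the planted default
  will not be reliably detected at n = 30 per group.
* Clustering responds non-monotonically to *mild* hub attenuation under
  proportional thresholding (dropped edges are replaced by
  triangle-rich within-module edges); the planted defaults sit in the
  monotone regime, but users exploring small attenuations should expect
  this.
* Louvain is a greedy heuristic; optimality is only guaranteed-by-test
  on tiny graphs, and modularity values on 82-node graphs carry the
  usual restart variability (suppressed, not eliminated, by 10 seeded
  restarts).
* The homologous-region merge assumes left/right nodes of the same name
  are comparable; a real atlas with asymmetric parcels would need a
  mapping table.
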