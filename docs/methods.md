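# Methods

## Problem and model

`scnkit` analyzes expertise-related reorganization of brain structural
covariance networks (SCNs) built from regional gray-matter volumes (GMV).
A classical SCN is a group-level object: its edge (j, k) is the Pearson
correlation, across subjects, between the covariate-adjusted volumes of
regions j and k. To recover per-subject networks, the package uses an
effect-size-difference (ESD) individualization: a control cohort defines a
normative reference (group SCN plus per-region mean and SD of residuals),
each subject's regional deviations are z-scored against that reference, and
the group SCN is modulated edge-wise by how similarly the subject deviates
at the two endpoint regions.

### Network construction

1. **Residualization.** Per region, volume is regressed (OLS with
   intercept) on the covariates — age, sex and total intracranial volume by
   default — over the *control* subjects only; residuals for every subject
   use those control-fit coefficients. Fitting on controls keeps group
   effects out of the adjustment and makes the reference truly normative.
2. **Group SCN.** Pearson correlations of control residuals; symmetric,
   unit diagonal.
3. **Control reference.** Per-region mean and sample SD (denominator n−1)
   of control residuals. Zero-variance regions are an error, not a warning:
   they make the z-score undefined.
4. **ESD weights.** For subject i with z-scores `z`, the inter-regional
   effect-size difference is `|z_j − z_k|` and the weight is
   `W_jk = exp(−|z_j − z_k|)`. The exponential form is a package
   convention: it is 1 exactly when the subject deviates identically at the
   two regions, decays smoothly, and is bounded in (0, 1]. The transform is
   pluggable (`1/(1+d)` is also shipped) because the literature does not
   fix a single formula.
5. **Individualization.** Element-wise product `W ⊙ SCN_control`. Since
   W ∈ (0, 1], individual edges keep the group edge's sign and can only
   shrink — a subject can lose normative covariance, not invent it. A
   subject sitting exactly at the control mean reproduces the group SCN
   bit-for-bit; this identity is a tested invariant.

### Topology over the sparsity grid

Weighted individual SCNs are binarized at sparsity levels K = 0.14 … 0.50
(step 0.01, 37 levels): the `round(K·n(n−1)/2)` strongest edges are kept
(round-half-away-from-zero). Ranking uses **absolute** weight by default
(negative covariance competes on magnitude; a positive-only mode is a
config switch) with lexicographic (row, col) tie-breaking, so edge sets are
deterministic and nested in K. At each level the package computes global
clustering coefficient (Cp), characteristic path length (Lp), global
efficiency (Eg) and local efficiency (Eloc), plus nodal variants and nodal
degree and betweenness centrality (unnormalized; each unordered pair
counted once). Conventions for degenerate cases:

* Lp averages finite distances only; unreachable pairs are excluded rather
  than assigned a penalty constant (grid validation separately enforces
  near-full connectedness), and a fully isolated node has nodal Lp 0.
* Lp is the arithmetic mean of shortest-path lengths — the conventional
  characteristic path length; the harmonic-mean notion of distance is
  already captured by Eg.
* Nodal Cp is 0 for degree < 2; nodal Eloc is 0 for < 2 neighbors.

Each metric-vs-K curve is summarized by its composite trapezoidal AUC
(width 0.36 at the default grid), the quantity entering all statistics.

Grid validity is screened per K: (1) every network's largest connected
component must cover > 90% of nodes; (2) more than 95% of networks must
have small-world σ = (Cp/Cp_rand)/(Lp/Lp_rand) > 1, with reference values
averaged over degree-preserving rewired surrogates (double-edge swaps,
10 × |E| attempts per surrogate). The standalone σ routine defaults to 100
surrogates; the full-grid screen uses 20 per network (and the bundled
acceptance run 10) because the screen only needs a coarse pass/fail
fraction, not a precise σ — per-network σ at 100 surrogates across 37
levels and a whole cohort would spend minutes to answer a yes/no question.

### Group statistics

Group differences of AUCs use a two-sided permutation test on the
difference of means: 5000 label permutations by default, with the add-one
correction p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1), so p is never 0; when
the number of distinct label splits is below n_perm the test switches to
exhaustive enumeration and reports the exact p. Benjamini–Hochberg FDR is
applied *within families* — the global metrics form one family, each nodal
metric one family across its nodes (a pooled mode is available). Cohen's d
uses the pooled-SD denominator. Correlations are Pearson when both
variables pass Shapiro–Wilk normality at p > 0.05, Spearman otherwise.

### Mediation

The three-variable model X (training duration) → M (a topology AUC) → Y
(strokes per round) is fitted on z-scored variables, so paths a, b, c, c′
are standardized betas and c = c′ + a·b holds exactly (a tested 1e−10
invariant). The indirect effect a·b is tested by resampling subjects with
replacement (5000 draws by default) and a bias-corrected (BC, no
acceleration term) percentile interval; degenerate resamples (a constant
variable) are redrawn up to 10 times. Candidate mediators must show a
significant group difference and significant correlations with both X and
Y; the global Cp model is always fitted in addition, as the primary
confirmatory model. By default the mediation sample is the two golfer
groups (controls have no stroke outcome); the choice is configurable.

## Synthetic cohorts

The generator emulates a three-group motor-expertise design: 20 experts,
20 novices, 20 controls; 116 regions (AAL labels) by default, 16 regions
with 4 covariance modules in the fast test configuration.

* **Volumes.** Multivariate normal on the log scale, then exponentiated —
  volumes are positive and approximately log-normal. The latent correlation
  is block-modular: within-module 0.60, between-module 0.08 (8 modules at
  116 regions). Deterministic base volumes span ≈3000–12000 mm³; the
  latent log-scale SD is 0.06.
* **Covariate confounds.** Log-scale effects per standardized covariate:
  age −0.02, sex 0.03, TIV 0.15. TIV deliberately dominates the latent
  dispersion, as it does in real morphometry, so raw volume correlations
  are confound-inflated and only residualized ones recover the block
  structure — exactly the failure mode residualization exists for.
* **Demographics.** Age ~ N(27.4, 3.1)/(27.1, 2.8)/(27.6, 2.2) per group;
  sex coded 0/1 and balanced within group (the emulated design matched
  gender but reports no breakdown, so balance is a convention); TIV ~
  N(1.45×10⁶, 1.3×10⁵) mm³. Training duration ~ N(12.4, 1.2) years for
  experts, N(1.8, 1.1) for novices (clipped at 0), 0 for controls.
* **Tightness mechanism.** Each subject's latent deviation pattern is a
  mixture `√(1−w)·ε + √w·u`, where ε has the block covariance and u is
  shared within each module. The mixing weight w ∈ [0, 0.95] is the
  subject's "network tightness": larger w makes deviations coherent within
  modules, which raises the within-module ESD weights and therefore
  clustering and local efficiency of the individualized network. Controls
  have w = 0, so their correlations converge to the generating block spec.
* **Mediation chain.** For golfers, z-scored duration X drives a latent
  unit-variance mediator M (path a = 0.33 by default), w = 0.35 + 0.20·M
  plus a planted group offset (+0.25 experts, −0.15 novices), and the
  standardized stroke outcome is c′·X + b·M + noise (b = −0.31,
  c′ = −0.22 by default — the effect pattern of the emulated study).
  Strokes are an affine map of that standardized outcome anchored at the
  pooled group stroke means/SDs (72.05 ± 4.3 and 86.15 ± 5.63): when the
  causal chain is active the group stroke gap *emerges* from the chain
  rather than being drawn independently, so the group moments are anchors,
  not exact reproductions. With the chain disabled, strokes are drawn
  directly from the group normals.
* **Planted group offset rationale.** With a = 0.33 the mediator is mostly
  noise by construction (its unit variance is a modeling requirement), so
  duration alone cannot move w far enough to separate groups of 20 on Cp
  reliably; the deterministic offset encodes the designed condition
  "experts have tighter within-module covariance". The offset sizes were
  fixed once, by simulation at design time, to make the planted direction
  detectable at the emulated sample size, and are part of the frozen study
  conditions.
* **Ground truth.** The generating covariance, planted effects, latent
  mediator, mixing weights and true indirect effect (a·b) are returned for
  testing; the analysis never sees them.

### What the generator does not emulate

Scanner/preprocessing artifacts, spatial smoothness, non-Gaussian volume
distributions beyond log-normality, site effects, age-nonlinearity, and
hub-like degree heterogeneity of real cortical networks. Passing tests
therefore certify the statistical machinery under the assumed generative
model, not neuroanatomical claims.

## Numerical and design choices

* Edge counts at sparsity K: round-half-away-from-zero; ties in edge
  ranking broken lexicographically — both make binarization deterministic.
* Exhaustive permutation switch-over: automatic whenever
  C(n_a+n_b, n_a) ≤ n_perm.
* BC bootstrap: the bias proportion is clipped to
  [1/(B+1), B/(B+1)] before the normal quantile to avoid infinite z0.
* All randomness flows from one root seed through named per-stage
  substreams (`numpy.random.SeedSequence`), so stages can be rerun from
  cached files byte-identically.
* Graph internals: distances via sparse BFS (`scipy.sparse.csgraph`),
  betweenness and surrogate rewiring via `igraph`; the test suite checks
  every metric against brute-force enumeration oracles and `networkx`.
* Problem sizes in the bundled tests and acceptance run (16 regions / 4
  modules for repeated-simulation checks; one full 116-region cohort; 500
  bootstrap draws and 1000 permutations inside repeated-simulation loops;
  10–20 rewiring surrogates in grid screens) are the package's chosen
  desk-scale study conditions; single confirmatory runs use the full 5000
  permutations and 5000 bootstrap draws.

## Known limitations

* The ESD-to-weight transform is a declared convention; published variants
  of individualized SCNs differ and are only partially supported (one
  alternative transform, no KL-divergence or partial-correlation schemes).
* The mediation model is the bare three-variable design — no covariates by
  default, no multiple mediators, no causal sensitivity analysis.
* Because individualized edges only shrink group edges, metric differences
  between individuals are driven entirely by deviation patterns; the
  method cannot express subject-specific covariance absent in controls.
* At 16 regions the low end of the sparsity grid often fragments networks
  (and is flagged by validation); the full grid is meaningful at
  atlas-scale node counts.
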