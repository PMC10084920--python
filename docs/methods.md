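# Methods

This note documents the models and procedures implemented in `luas`, the
defaults they ship with, and what the synthetic test-bed does and does not
establish about real data.

## The scientific setting

Lung adenosquamous carcinoma contains both adenomatous and squamous
pathology in one tumor. Two observations motivate the toolkit's design:
shared truncal somatic variants between microdissected components argue for
a monoclonal origin with an adeno→squamous lineage transition (rather than
a collision of two tumors), and transcriptome ordering of tumors along an
adeno→squamous axis shows an inflammatory intermediate whose gene
covariance structure behaves like a critical transition. The package
provides the statistics used to make each of those arguments, plus a
mechanistic model of the transcription-factor circuit believed to control
the switch.

## Single-sample enrichment score

For a sample with G genes and a gene set S, genes are converted to average
ranks (ascending; the highest-expressed gene has rank G). Walking the genes
in descending expression order (ties broken by gene id), the score is

    score = Σ_i [ P_in(i) − P_out(i) ]

where P_in is the cumulative normalized in-set weight, with gene weights
rank^τ, and P_out the cumulative fraction of out-of-set genes. τ defaults
to 0.25; τ = 0 weighs all set genes equally. The statistic is a function of
within-sample ranks only, hence invariant under any strictly monotone
transform of one sample's expression — the property the tests check with
random monotone maps. When S contains every gene the out-of-set ECDF is
undefined and the score is pinned to 0. This single-sample running-sum
variant was chosen over a cohort-level kernel-density variant because it
needs no cross-sample estimation and is rank-exact on small matrices; the
weight exponent is exposed for sensitivity analysis.

Subtype assignment is deliberately simple: a sample is *inflammatory* when
its immune score exceeds a threshold (default: the cohort's upper tercile),
otherwise *TRU-like* when the adenomatous score ≥ squamous score, else
*basal-like*. This reproduces a three-class split without a consensus
clustering dependency; it is a thresholding surrogate, not a clustering.

## Sliding-window DNB analysis

Samples are ranked by the squamous score and scanned with windows of 10
samples, step 1 (window size matches the scale at which the transition is
expected to be visible; both are configurable). Within a window:

1. genes with window SD at or above the 0.75 quantile are kept;
2. kept genes are clustered by average-linkage on distance 1 − |Pearson r|,
   cut at height 0.4 (i.e. mean within-cluster |r| ≈ 0.6);
3. clusters of ≥ 3 genes are candidate modules;
4. each module m gets the composite index
   CI(m) = SD_in · PCC_in / max(PCC_out, 1e−6),
   with SD_in the mean within-module sample SD (ddof = 1), PCC_in the mean
   |r| over distinct module pairs, PCC_out the mean |r| between module and
   non-module genes. Genes with zero window variance contribute r = 0.

The window trace records the best module per window; the tipping point is
the argmax-CI window, ties resolved to the earlier window. The ε guard on
PCC_out only matters in degenerate windows and is flagged in the trace.
Numerical notes: CI scales linearly under multiplication of the matrix by
c > 0 (through SD_in only); a window of constant genes yields no modules
and CI = 0; the trace is serialized with all three components for audit.

One module is selected per window rather than pooling clusters across
windows; with step 1 the same underlying module is rediscovered by every
window that overlaps the burst, so pooling adds little and obscures the
per-window index.

## Four-TF network model

State x = (N, F, P, S) for NKX2-1, FOXA2, TP63, SOX2 (arbitrary units).
Production of each TF is a multiplicative Hill gate — activation by its
within-lineage partner times repression by each cross-lineage TF — plus a
basal rate b, with linear degradation d:

    dN/dt = b + α_A H⁺(F) H⁻(P) H⁻(S) − dN      (F symmetric in N)
    dP/dt = b + α_S H⁺(S) H⁻(N) H⁻(F) − dP      (S symmetric in P)

H⁺(y) = yⁿ/(K_actⁿ + yⁿ), H⁻(y) = K_repⁿ/(K_repⁿ + yⁿ). The FOXA2 ⊣ SOX2
edge is repression-only, symmetric with the other cross edges. This
functional form is the package's own reconstruction of the circuit topology;
the multiplicative gate with shared constants per interaction class is the
most parsimonious choice consistent with the wiring.

Defaults: α_A = 2, b = 0.3, K_act = 0.5, K_rep = 1.0, n = 2, d = 1,
σ = 0.05. They were fixed by a coarse parameter search for the
qualitative behaviour the model must exhibit, and then frozen:

- with α_S as the scanned parameter, the regime sequence over
  α_S ∈ [0, 2α_A] is adenomatous-monostable → bistable →
  squamous-monostable (boundaries ≈ 1.55 and ≈ 3.95);
- at α_S = α_A the two attractors are exact mirror images under
  (N,F) ↔ (P,S);
- no additional "all-low" attractor exists (this requires b ≳ 0.2 and
  shallow repression; with steep repression, n ≥ 3 and K_rep ≪ 1, the
  adenomatous state never destabilizes and the squamous-monostable regime
  is unreachable).

These are model choices, not fitted constants, and all are configurable.

Fixed points come from multi-start root finding (Latin-hypercube starts in
[0, x_max]⁴ plus deterministic corner/center probes, x_max = (b + α_max)/d),
deduplicated within 1e−3; stability from the real parts of the eigenvalues
of a central finite-difference Jacobian (relative step 1e−6). Regimes are
labeled from the stable states' lineage projection
u = (N+F)/2 − (P+S)/2: adenomatous-like if u > 0.1, squamous-like if
u < −0.1.

Stochastic dynamics: Euler–Maruyama with additive isotropic noise
σ√dt·ξ and a reflecting boundary at 0 (|x| after each step); dt = 0.01
with the explicit-Euler guard dt·d < 0.1. The landscape is
U = −ln(P_ss + ε), ε = 1e−12, where P_ss is the normalized 2D histogram of
post-burn-in states (burn-in fraction 0.2) projected to
u (adeno-minus-squam) and v (mean of all four). Two practical notes: for
symmetry checks the u-range must be chosen symmetric about 0 so mirror
cells align exactly (auto-ranged edges misalign mirror bins across steep
potential walls), and potential differences are only meaningful on cells
with adequate occupancy — the tests use P_ss ≥ 2×10⁻³.

## Deconvolution

With exactly two reference centroids m_A, m_S (log2 scale), the
simplex-constrained least-squares problem is one-dimensional:
f_adeno = ⟨y − m_S, m_A − m_S⟩ / ‖m_A − m_S‖², clipped to [0, 1] —
exact, deterministic, no iterative solver. Centroids come from labeled
reference samples (per-gene means) or from indicator profiles of gene
sets. Log2 space is the default and a deliberate choice: the scores it is
correlated against are rank-based, and mixing linearity in log space is the
assumption that the recovery tests exercise. Correlations with immune
scores use Pearson r with the two-sided t-based p and BH-FDR across sets.

## Cohort genomics

*Fisher testing.* Each event pair forms a 2×2 table; the two-sided p sums
all hypergeometric tables no more probable than the observed one (the
classical convention; equals `scipy.stats.fisher_exact` and is verified in
the tests against an independent enumeration with binomial coefficients).
The odds ratio is Haldane-corrected (+0.5 per cell) whenever a cell is
zero. BH-FDR across tested pairs; relation = co-occurrent if OR > 1 else
exclusive.

*Printed-count arithmetic.* `contingency_percent` rounds
half-away-from-zero, matching how the cohort's percentages are printed
(e.g. 120/5676 → 2.1%, 20/40 → 50%).

*Signature NMF.* The 96-context catalog (pyrimidine-centered contexts,
lexicographic within substitution class) is factorized by multiplicative
updates under generalized Kullback–Leibler divergence, best of 20 restarts;
the update monotonicity is asserted on every run. Signatures are
L1-normalized, exposures renormalized per sample, signatures ordered by
total exposure, and optionally matched one-to-one to reference profiles by
maximal cosine (Hungarian assignment). The number of signatures k is user
input; no automated model-order selection is attempted.

*CCF and origin.* CCF_raw = VAF·(p·CN + (1−p)·2)/(p·m), capped at 1 with
the raw value retained; at p = 1, CN = 2, m = 1 this reduces to 2·VAF.
When depth is available, a two-sided Wilson 95% interval on the VAF is
propagated linearly to the CCF scale. A variant is flagged clonal when the
upper bound of that interval reaches the clonal region (≥ 0.9) — i.e. the
data cannot confidently exclude clonality — which is the usual convention
in clonality analysis; requiring the *lower* bound to clear 0.9 would
misclassify genuinely clonal variants at any realistic depth.
`classify_origin` calls a tumor monoclonal when the shared-variant fraction
(shared/union) ≥ 0.1, and infers direction from the shared variants: if
the fraction clonal-in-squamous-but-subclonal-in-adenomatous exceeds the
converse by 0.2, the squamous lesion is inferred to derive from an
adenomatous subclone (*adeno_first*). Both thresholds are free parameters.
Per-variant CCF thresholding is used rather than mutation-cluster mixture
modelling; with trunk sizes in the tens to hundreds this is ample for the
direction call, but it does not resolve subclonal structure.

## Synthetic cohort generator

The generator emulates the *structure* the statistics need, not RNA-seq
realism:

- samples at equally spaced latent coordinates t ∈ [0, 1] (equal spacing
  makes window indices deterministic for tests);
- adenomatous/squamous markers follow decreasing/increasing logistic
  profiles in t (amplitude 4, steepness 10, on a log2 baseline of 5 with
  Gaussian noise SD 0.5);
- immune genes carry a wide, low Gaussian bump at the tipping position
  (amplitude 1.5, width 0.1) — wide and low so that immune genes mark the
  inflammatory samples without themselves forming a high-variance
  correlated module that would compete with the DNB signal;
- DNB genes (default 25, comparable to the ~31-gene module reported at
  cohort scale) are flat on average but, inside a ±half-window band around
  the tipping position, load on a shared two-state factor (±1, unit
  variance) with loading chosen so that within-band SD is
  √(0.5² + 1.0²) ≈ 1.12 and pairwise correlation is exactly the configured
  target (default 0.8) by the single-factor identity
  corr = λ²/(λ² + σ²). The two-state factor (rather than a Gaussian one)
  models samples occupying one of two transient regimes at the tipping
  point; practically, its constant magnitude keeps the composite-index
  peak localized — a heavy-tailed factor draw lets a single extreme sample
  dominate the correlation estimates of partially overlapping 10-sample
  windows and smears the peak by several windows;
- subtype labels are assigned from t: inflammatory within the burst band,
  TRU-like below, basal-like above;
- alteration tables plant exclusivity by resolving double-positives with
  the stated probability and co-occurrence through a shared Bernoulli
  driver with marginal-preserving top-up rates;
- mutation catalogs are multinomial draws from signature mixtures;
- paired variant sets place the trunk clonal in the squamous component
  (CCF = 1) and subclonal in the adenomatous one (CCF ~ U(0.3, 0.7)),
  with VAFs back-computed through the CCF formula at CN = 2, m = 1 and
  binomial read sampling (default depth 100, purity 0.9 — microdissected
  components are near-pure).

What passing tests show — and what they do not: planted-recovery results
demonstrate that the implementations detect exactly the structure they are
designed to detect at realistic sizes (93 samples, 10-sample windows,
module correlation 0.8). They do not show that real LUAS cohorts contain
such a burst, nor calibrate effect sizes against the access-controlled
cohort data; the generator's variance structure is an order-of-magnitude
choice, not a fit.

## Packaged fixtures

Count tables printed in the cohort description (collection totals, stage
and smoking distributions, EGFR/ERBB2 allele counts, ALK fusion counts,
the mouse-model transition penetrance) ship as JSON with provenance
strings. Two counts are not printed directly and are back-computed from a
printed percentage and total (non-smokers: 46.8% of 109 → 51; mouse
transition: 75% of 8 → 6); these carry `derived_count=true`.

## Pipeline and seeds

`run_pipeline` chains generation → scoring → ranking → DNB → deconvolution
→ TF model → fixture statistics into one JSON/Markdown report. One global
seed fans out to per-module seeds via
`SeedSequence([global_seed, module_offset])` reduced to 31 bits, so
changing one module's stream leaves the others untouched. The landscape
stage of the pipeline runs a reduced simulation (40 trajectories, T = 200)
— enough to locate the wells for reporting; use `luas tf landscape` for a
production-quality surface.

## Known limitations

- The TF model is a qualitative reconstruction: topology-faithful, but no
  parameter is fitted to data, and conclusions should be read at the level
  of regime structure, not rate constants.
- Subtype assignment is a thresholding stand-in for consensus clustering.
- The deconvolution is strictly two-component; immune content is handled
  by enrichment scores, not fractions.
- DNB module discovery inherits the instability of correlation estimates
  on 10-sample windows; occasional off-by-a-few-windows peaks and small
  spurious high-correlation modules are expected behaviour of the method
  at this window size, visible in the ~95% (not 100%) planted-recovery
  rate.
- No survival analysis, driver-significance modelling, copy-number
  segmentation or fusion calling is included.
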