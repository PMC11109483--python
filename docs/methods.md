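# Methods

This note documents the statistical model, the conventions and defaults the
package commits to, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reproducing results.

## Data model and preprocessing

Quantification enters as a protein-isoform × sample matrix of linear-scale
iBAQ intensities with an explicit missingness mask; zero and empty cells are
treated as *not quantified* (the MaxQuant convention — iBAQ 0 carries no
abundance information). Each table row is one analysis unit; no isoform
re-grouping is attempted, and gene-level interpretation is left to the
caller. Statistics never read masked cells: masked entries are stored as NaN
so that any accidental use fails loudly.

The preprocessing chain runs in a fixed order:

1. **Flag filtering.** Rows flagged reverse (decoy), contaminant or
   identified-by-site-only are removed before anything else.
2. **Dropout-sample removal.** A sample is discarded when its present-value
   count falls below 0.5 × the median present-count of samples in its
   dataset. The 0.5 fraction is this package's convention — "dropout sample"
   has no standard quantitative definition — and removal that would leave a
   bait group with fewer than two replicates is an error rather than a
   silent degradation.
3. **Valid-value filtering** (default `min_valid = 3`): a protein is kept
   when at least one bait group (bead control included) holds ≥ 3 quantified
   replicates. *At least one* group, not all groups: bait-exclusive binders
   are precisely the objects of interest and would be discarded by an
   all-groups rule.
4. **Log2 + median normalization.** Present values are log2-transformed and
   each sample is shifted so its median equals the grand median of
   per-sample medians. Any constant anchor gives identical downstream
   statistics (group-mean differences are shift-invariant); the grand median
   keeps values on a familiar scale. Normalization is idempotent and never
   touches the mask.
5. **Downshift imputation** (defaults `shift = 1.8`, `width = 0.3`, per
   sample): each missing cell in sample *s* is drawn independently from
   N(m_s − 1.8·sd_s, (0.3·sd_s)²), where m_s and sd_s are the mean and SD of
   the sample's present log2 values. These two constants are the de-facto
   convention for this imputation family; both are exposed in the config.
   Imputation is seeded, never alters present cells, and records an
   imputation-provenance mask. Per-sample (rather than dataset-wide)
   distributions are used, the standard choice when column loads differ.

## Moderated statistics

For protein *g* the one-way layout across bait groups yields group means
μ̂_{g,k}, a pooled within-group variance s²_g and residual degrees of freedom
d_g = N − K (variance is pooled across *all* groups of a dataset, matching
the all-pulldown F framing and maximizing d_g). The hierarchical model
places a scaled inverse-χ² prior on the true variances,

    s²_g | σ²_g ~ σ²_g · χ²_{d_g}/d_g,      1/σ²_g ~ χ²_{d₀} / (d₀ s₀²),

so that marginally s²_g/s₀² ~ F(d_g, d₀). The posterior-mean (moderated)
variance is

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),

and the moderated t and F statistics replace s²_g by s̃²_g and gain d₀
denominator degrees of freedom. (d₀, s₀²) are estimated by moment matching
on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of Var(e) over the
mean of ψ′(d_g/2) identifies ψ′(d₀/2), inverted by monotone Newton
iteration; s₀² follows from the mean of e with the digamma correction.

Numerical conventions:

- A non-positive excess variance of log s² means no detectable variance
  heterogeneity; the prior degenerates to d₀ = ∞ (s̃² ≡ s₀², effective df
  capped at 10⁶, Normal-like tails). Fewer than 10 usable variances triggers
  the same fallback with a warning.
- Zero sample variances (constant rows) are excluded from prior estimation
  but still receive a positive moderated variance through the d₀s₀² term.
- d₀ = 0 is admitted as the no-moderation limit and reproduces the classical
  pooled two-sample t and one-way ANOVA F exactly — this limit is the
  oracle the test suite checks against.
- Each contrast's p-vector is BH-adjusted (step-up with running-minimum
  enforcement) across the proteins in that contrast. The variance prior is
  estimated once per processed matrix; the prefilter pass and the final pass
  therefore each get their own prior, since their matrices differ.

## Two-pass prefilter and classification

The bead-control prefilter decides membership on fully processed data
(pass 1: normalize, impute, moderated t of each bait vs bead control; keep
adj. p < 0.05 and logFC > 0 in ≥ 1 contrast) and then re-processes the raw
filtered matrix subset to the retained proteins (pass 2), so that
normalization and imputation are conditioned only on Ub-enriched proteins.
The two imputations draw from independent substreams of the run seed. The
enrichment direction is logFC > 0 (enriched on Ub over empty beads); a
protein depleted on Ub versus beads is not a Ub interactor.

Classification rules are pure functions of contrast tables (all at
adj. p < 0.05):

- **Linkage**: K48 Ub3 vs K63 Ub3; significant positive → K48, negative →
  K63; datasets conflicting in direction → unclassified.
- **Length**: Ub3 vs Ub2 per linkage; significant in ≥ 1 dataset *and*
  fold-change consistent in every dataset supplied — |logFC| > 0.5 for K48,
  sign only for K63. The asymmetric thresholds mirror the observation that
  K48 length effects are larger and noisier than K63 ones; both Ub3- and
  Ub2-preferring directions are reported, and conflicting calls across
  linkages are both kept.
- **Branch**: branched trimer vs both homotypic trimers significant positive
  within a dataset → branch-specific; all four Br-vs-homotypic contrasts
  (Ub2 and Ub3, both linkages) in every dataset → strict tier; both trimer
  contrasts reversed → homotypic-preferring. A protein triggering opposite
  tiers in different datasets stays unclassified.

For clustering and between-dataset correlation, the per-pulldown summary of
a protein is its fitted group mean from the one-way layout, z-scored per
protein. (A moderated F value is one number per protein, not per pulldown,
so "per-pulldown moderated values" can only mean the per-group model
values.) Clustering is agglomerative with Euclidean distance and complete
linkage on row-z-scored profiles, cut at a user-chosen k (no automatic k
selection); constant rows are dropped with a warning. Correlation is
Spearman's ρ per bait pair over the common significant proteins (≥ 3
required).

Annotation enrichment uses the disjoint-category 2×2 table (filtered vs
not-filtered), which counts every protein exactly once, with the two-sided
exact hypergeometric p (sum of outcome probabilities ≤ the observed one);
one-sided alternatives are available.

## Synthetic data

The generator emulates the study design: a bead-only control plus six Ub
chain baits (mono-Ub, K48/K63 Ub2/Ub3, K48/K63-branched Ub3) in
quadruplicate, optionally as two datasets sharing one planted truth with
independent noise — the two-inhibitor (CAA/NEM) structure. Log2 intensity
is baseline + class-specific per-bait effect + N(0, σ_rep²), exponentiated
to a linear scale and thinned by intensity-dependent dropout
P(miss | x) = 1/(1 + exp(β(x − γ))).

Defaults, chosen once as plausible for deep pulldown proteomes: baseline
N(25, 2²) log2 iBAQ; σ_rep = 0.4; MNAR midpoint γ = 22 and slope β = 1
(≈ 10% missing cells overall); 2,000 proteins of which 70% background, 5%
each bead binders, pan-Ub binders, K48- and K63-specific binders, and 2.5%
each length-dependent (per linkage), branch-specific and branch-excluded
binders; 1% reverse and 1% contaminant decoy rows. Effect sizes: preferred
bait δ = 3 log2 units; length-dependent classes add +1.5 on Ub3 over Ub2;
branch-specific binders see Br Ub3 at 3 with homotypic trimers at 1;
branch-excluded binders the reverse; bead binders stick to everything
(control included) at 2. These separations are comfortably detectable at
n = 4 with σ_rep = 0.4, mirroring clearly separated cluster structure.

Because the planted effect vector of every protein is retained, recovery is
scored against the generator itself: a call is a true discovery exactly when
the protein's planted effects satisfy that rule's population definition
(e.g. the branch-specific pattern above genuinely supports a Ub3-length call
too, since its homotypic trimer effect exceeds its dimer effect).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: peptide-level quantification noise and
protein-inference ambiguity, correlated missingness within runs, batch
effects, abundance-dependent variance trends, indirect interactors recruited
via complexes, and bait-input imbalances (e.g. partial chain disassembly in
lysate). Real-data behaviour of the statistics, not their correctness, is
what those phenomena would change.

The SPR simulator produces 1:1-binding multicycle sensorgrams
(R(t) = Req(1 − e^{−(k_on C + k_off)t}) during association, exponential
k_off decay after) and equilibrium series on the hyperbola
Req = C·Rmax/(K_D + C) with additive Gaussian read noise (default 0.5 RU,
Rmax = 100 RU). The default concentration grid is a two-fold series,
0.061–250 µM (13 points), matching the study's injection range. Bivalent or
mass-transport-limited binding is out of scope.

## SPR fitting conventions

Equilibrium responses are averaged over the final 5 s of the association
window (the vendor software's window is unpublished; 5 s is this package's
convention) with a plateau check: the least-squares slope over the window
must be below 0.2 RU/s in magnitude, otherwise the point is flagged — not
dropped. Fitting minimizes unweighted squared residuals over
K_D ∈ [10⁻⁴, 10⁴] µM and Rmax ∈ (0, 10·max Req], initialized at
Rmax₀ = max Req and K_D₀ = the interpolated concentration at half-maximal
response, with a 7×7 log-grid multi-start to escape the flat likelihood of
the weak-binding regime. Triplicates are fitted independently; the reported
affinity is the mean per-replicate K_D with its sample SD (matching the
"K_D ± SD over triplicates" reporting convention), alongside a pooled
all-points fit. A fitted K_D above the highest injected concentration sets
a saturation flag: the affinity is outside the tested range and the estimate
is weakly constrained — such values are reported but must be read as
approximate.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at the
study's own scale: 2,000-protein, 7-bait × 4-replicate datasets (two per
study) for end-to-end recovery; 5,000-protein null simulations for type-I
calibration; 10⁴ draws for prior-recovery and imputation-moment checks; and
13-point triplicate series for affinity recovery. The acceptance script
pools end-to-end recovery over three independent replicate studies so that
per-class sensitivity rests on 150 planted members rather than 50.

## Known limitations

- The moderation scheme is the canonical published one; equivalence to any
  specific external tool's variant is not claimed.
- The length/branch rules threshold point estimates of logFC; no shrinkage
  of fold changes is applied before thresholding.
- Downshift imputation inflates within-group variance for proteins whose
  missing cells are imputed far from their observed values; weakly detected
  true binders can lose their contrast for this reason (the recovery tests
  quantify the effect rather than hide it).
- Gene Ontology enrichment is out of scope; the package exports per-cluster
  gene lists for external tools.
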