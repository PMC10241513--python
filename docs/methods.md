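# Methods

## Mixed-model association

The association model for a strain-level response y is
y = Xb + x_j g + u + e with u ~ N(0, σ_g² K) and e ~ N(0, σ_e² I). The
kinship matrix K = ZZ'/M is computed from all polymorphic markers after
column standardization (no leave-one-chromosome-out by default; the kinship
therefore contains the tested marker, a conservative choice at 2000 markers).
Fitting follows the factored-spectral strategy: K is eigendecomposed once per
trait, the variance ratio δ = σ_e²/σ_g² is maximised by ML under the null on
a 100-point log grid over [1e-5, 1e5] refined by golden section (relative
tolerance 1e-6), and δ is then held fixed for all markers. Each marker adds
one fixed effect in the rotated model; the test is LRT = n·ln(RSS₀/RSS₁)
against χ²(1), and LOD = LRT/(2 ln 10). ML rather than REML is used because
the LRT compares models with different fixed effects.

Assumptions: homozygous biallelic genotypes (inbred panel), Gaussian
residuals on the log-abundance scale, a single variance ratio per trait
shared across markers (the standard speed approximation; per-marker
re-optimisation changes p-values negligibly at these sample sizes).

Missing abundance values are handled per feature by complete-case analysis:
strains missing that feature are dropped and K is sub-matrixed. Features
sharing a missingness pattern share one eigendecomposition. Markers
monomorphic on the analysis subset, or collinear with the covariates, are
emitted with p = 1, beta = 0 and a flag rather than dropped, so record
counts are stable across features.

Thresholds: genome-wide significance p < 4.1e-6 (a fixed constant
established for this style of panel, configurable); cis window 1 Mb with
cis p < 1e-5; trans p < 1e-6. Cis-eligibility takes precedence — a
sub-window association is never counted as trans, however strong. A
permutation-threshold utility exists but is off by default.

## Hotspot calling

Per feature and class, the peak is the minimum-p record. Hotspots are called
per chromosome by 4-Mb windows advancing in 2-Mb steps; a window qualifies
when the trans peaks of at least 10 distinct features fall inside, and
overlapping qualifying windows are merged (so a cluster straddling a window
boundary yields one call). The call's peak marker is the member peak with
the smallest p in the merged interval. Windows are half-open [start, end) on
1-based coordinates. The window size and member floor are declared package
defaults — chosen so hotspots with 20–30 members are unambiguous — not
inferred quantities; both are configurable.

## Co-expression modules

bicor follows the standard biweight midcorrelation: median-centring, Tukey
biweight on u = (x − median)/(9·MAD) with unscaled MAD, weights zero for
|u| ≥ 1. A zero MAD invalidates the biweight for the whole pair, which then
reverts to Pearson. Under missingness each pair uses its complete cases
(minimum 3, else adjacency 0 with a warning). The network is unsigned,
adjacency |bicor|^β with β = 6, and clustering is average linkage on
1 − TOM with a static cut.

The static cut height defaults to 0.9. The within-module TOM dissimilarity
of a module with inter-member correlation r ≈ 0.8 under β = 6 is ≈ 0.7, so
any cut below that (e.g. the 0.25 sometimes quoted, which is an eigengene
*merge* height, not a tree-cut height) would shatter real modules into
singletons; 0.9 separates planted modules (distances 0.2–0.8) from the
noise background (pairwise distances ≈ 1) across the regimes the generator
produces. Clusters below the minimum size (10) are pooled into the
unassigned ("grey") module. No eigengene-similarity merging of close modules
is performed. Module eigengenes are the first right singular vector of the
standardized member matrix over strains, scaled to unit (population)
variance and sign-aligned with the mean member profile; missing member
values are mean-imputed for the SVD only.

## Enrichment

Upper-tail hypergeometric p, accumulated in log space (gammaln + logsumexp)
so extreme overlaps do not underflow; Benjamini–Hochberg q across the tested
categories. The background defaults to all quantified features passing the
presence filter, not the genome. The modified one-sided EASE variant used by
some annotation servers is deliberately not replicated, so p-values from
such servers are not comparable targets.

## Mediation and founder effects

LOD-drop mediation compares y ~ 1 + c + locus against y ~ 1 + c by least
squares; the locus design is the allele dosage (1 d.f.) in the inbred panel
or the 7-column sum-to-zero founder-contrast design (7 d.f.) at a DO locus.
Because a single locus is analysed at a time, no kinship term is used in
DO-side scans; this is a simplification relative to full multiparent genome
scans and is adequate for recovery-based validation. Candidates collinear
with the locus design are flagged, not dropped; a candidate identical to
the target gives conditional LOD 0 by convention (the null already fits
exactly).

Under missingness, each candidate is evaluated on its complete cases with
the marginal LOD recomputed on the same subset. For ranking many candidates
against a hotspot, the package aggregates over all member targets and orders
candidates by mean *conditional* LOD (ascending): a true mediator drives
every target's locus signal to the null. With complete data this ordering
is identical to mean LOD-drop descending; under missingness it is preferred
because each candidate's complete-case subset shifts its marginal LOD by a
candidate-specific amount, which contaminates the drop across candidates
while leaving the conditional comparison fair.

Founder effects are least-squares coefficients of y on an intercept plus
the dosage matrix projected onto an orthonormal sum-to-zero basis,
back-transformed to the 8-vector (which sums to zero over estimable
founders); absent founders are flagged unestimable. Concordance between two
effect vectors is their Pearson correlation over founders estimable in both.

## Synthetic data: what it emulates, and what it does not

`simulate_panel` draws strains from k ancestral clusters: per marker, an
allele frequency from the MAF range, one ancestral allele per cluster, and
per-strain flips with probability `flip_prob`. This produces the two
features that matter for validity testing — block-correlated genotypes and
cluster-structured kinship — but not realistic local LD decay, recombination
maps or allele-frequency spectra. `plant_architecture` builds mediator
m = b_cis·g + ε and targets t = a_t·m + ε, so all marker-to-target signal
flows through the mediator by construction; background features are pure
noise; missingness is missing-completely-at-random (default 10% — the
mechanism is a declared choice, as only a presence filter is stated for the
real data; both complete-case and imputation-free regimes can be exercised
by setting the rate). Passing recovery tests therefore demonstrates the
statistical machinery under a faithful causal architecture, not robustness
to batch effects, peptide-level quantification noise, or confounded
missingness.

Default conditions (chosen once, as the study conditions): 72 strains, 2000
markers on 19 autosomes, 6 clusters, flip_prob 0.25; three hotspots of
26/22/26 targets with b_cis = 2.0, a_t = 1.5, noise 0.4 s.d., hotspot
markers restricted to MAF ≥ 0.35 and pairwise |r| ≤ 0.3. These effect sizes
put planted features at p ~ 1e-20s at n = 72 — the magnitude real proteome
hotspots exhibit — so label recovery is expected to be exact, and a failure
indicates an implementation defect rather than sampling noise. The DO locus
uses n = 500 mice, a 4-high/4-low founder pattern with contrast scale 0.27
and noise 0.5, calibrated analytically so the mediator LOD is ≈ 50,
matching the strongest signals reported for such hotspots; 14 targets with
unit loading then sit at LOD ≈ 25–30, strictly below the mediator.

The calibration experiment (genomic inflation) uses its own cohort: 100
strains, 6 clusters, flip_prob 0.15 — tighter cluster haplotypes modelling
the strong population structure of real inbred panels, under which naive
single-marker regression on a heritable (h² = 0.5) polygenic null trait
inflates to λ ≈ 2 while the mixed model stays within a few percent of 1.
The mixed model is calibrated at every structure level tested; the stronger
structure exists to make the *contrast* with naive mapping unambiguous.

All randomness flows from one integer seed through named substreams
(panel/abundance/trait/do), so each stage is independently reproducible and
identical seeds give byte-identical outputs.

## Numerical choices

- Eigenvalues of K clipped at zero; non-PSD beyond 1e-8·trace is an error.
- Scan degeneracy (collinear marker) detected at 1e-12 relative to the null
  RSS; such records get p = 1, beta = 0, flag set.
- p-values floored at 1e-300; LRT clipped at 0.
- Hypergeometric tails exact in log space; agreement with rational
  enumeration to 1e-10 relative for N ≤ 30 is enforced in tests.
- Ties in peak selection resolve to the first marker in map order.
- "Noiseless" direction checks use noise 0.05 s.d.: an exactly noiseless
  planted chain makes within-genotype variance zero and the pooled t-test
  undefined, so near-noiseless is the smallest regime where the test is
  well-posed (sign agreement is still deterministic at these effect sizes).

## Known limitations

- No LD-based clumping or conditional multi-signal dissection within a
  hotspot; one call per merged window.
- No covariates by default in the LMM (configurable), no multi-variance-
  component models, no epistasis.
- DO-side analysis is single-locus; no haplotype reconstruction or full
  36-genotype scans.
- Module construction uses a static cut; dynamic tree cutting and module
  merging are out of scope, so module *counts* on real data are not directly
  comparable to pipelines that merge close modules.
- The gene position used for cis classification is the annotated position
  as given (start-like); TSS-vs-midpoint distinctions are the annotation's
  responsibility.
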