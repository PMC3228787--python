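# Methods

This note documents the models, parameter choices and numerical decisions
behind `crmkit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open. Coordinates quoted from
published region tables (1-based inclusive) are converted on input
(`start − 1, end`); one convention everywhere prevents off-by-one drift,
and round-trip tests assert BED↔internal conversion is the identity.
Score tracks are read from bedGraph (gaps filled with 0, overlapping
intervals rejected); binary track formats (bigWig/bigBed) are out of
scope. Downstream property analyses of validated regions are anchored on
the *insert* coordinates (the sequence actually assayed), not the wider
prediction spans.

## Motif scanning

A position frequency matrix `C` (4×L counts) becomes a log-odds PWM with

    w[b,i] = log2( (C[b,i] + p·bg[b]) / (colsum[i] + p) / bg[b] )

with pseudocount `p = 0.8` distributed by the background `bg` (common
JASPAR practice; the choice only matters at near-zero counts). Score
bounds are per-column extreme sums, and a hit's relative score is
`(s − s_min)/(s_max − s_min)`, which is invariant under affine rescaling
of the weight matrix. Scans cover both strands at a default relative
threshold of 0.8, the convention of the muscle CRM scanners this package
models. `N` bases contribute the background-expected column weight, so
they neither reward nor punish a window. When same-motif hits overlap,
only the highest-scoring one is retained (greedy by descending score;
ties broken by leftmost start, then + strand, for determinism);
different motifs may overlap freely.

Motif-profile similarity is scored on the 0–2 scale (2 = identity) as the
best ungapped offset alignment of the two frequency matrices over both
orientations, requiring the overlap to cover at least half of the shorter
motif and scoring aligned columns by `2 − Σ_b |f_a(b) − f_b(b)|`. This
uses the L1 column distance rather than the original matrix-alignment
recursion, whose internals are not reproduced here; values from that
program are therefore comparable in spirit but not digit-for-digit.

## CRM prediction

Search regions follow the oPOSSUM construction: ±10 kb around each TSS,
minus coding exons and ±50 bp around alternative TSSs, clipped to
chromosome bounds. Candidate windows are 200 bp at a 50 bp step —
matching the scale of the validated insert cores (~220–400 bp) — and a hit
contributes to every window it intersects (no boundary loss). Two window
scores are produced:

* **LRA score** — a ridge-regularized (λ = 1e−3) logistic regression on
  {best relative score, hit count} per motif (2·n_motifs features plus
  intercept), fit deterministically. The ridge guarantees convergence on
  separable training data.
* **Cluster score** — the sum of relative scores of overlap-resolved hits
  minus a gap penalty times the uncovered window fraction; a generic
  additive stand-in for HMM-based cluster scorers, monotone in added
  hits at zero gap penalty.

Windows at or above a score cutoff are merged when adjacent/overlapping;
merging is idempotent and predictions never extend beyond the scanned
region. Predictions whose only hits are SP1 (GC-box) sites are removed —
SP1 matches are ubiquitous and carry no muscle specificity. An optional
conservation filter keeps only predictions whose maximum per-base
conservation reaches a cutoff (0.7 by default).

## Reporter-assay analysis

Raw wells carry firefly and renilla luminescence (LRU). QC follows the
screen's heuristic: wells with firefly < 1000 LRU fail ("above the
threshold" is treated as inclusive, so exactly 1000 passes); wells with
only renilla below 1000 have renilla set *to* 1000 before the ratio
firefly/renilla is taken, which bounds the ratio by firefly/1000 and
suppresses spuriously large ratios from near-background denominators.
Technical replicates are averaged; a single passing replicate is used
alone (flagged); a clone with both replicates failed is excluded for that
cell type.

Ratios are variance-stabilized with a generalized-log transform
`glog(x) = asinh((x − a)/b)`, with `(a, b)` fit by maximum likelihood
under a normal model for the transformed values (profiling out mean and
variance leaves `n/2·log var(h(x)) + ½·Σ log((x−a)² + b²)` to minimize;
Nelder-Mead, b bounded away from 0). One `(a, b)` pair is calibrated per
phase on the pooled ratios and applied to every cell type: per-cell-type
location/scale calibration is not identifiable from ~90 ratios per batch
and can translate batches arbitrarily, destroying exactly the
cross-cell-type contrast the differential test measures. With pure
multiplicative noise the fit approaches a log transform, which is the
correct stabilization in that regime.

Differential myotube expression is called per clone with a moderated
two-class statistic `d = (x̄_MT − x̄_other)/(s + s0)`: myotube wells
against pooled myoblast/fibroblast wells (phase 1) or myoblast wells
(phase 2), `s` the pooled standard error and `s0` the median of per-clone
`s`. The null distribution permutes sample labels globally — one
relabeling applied to every clone per permutation — and all distinct
relabelings are enumerated exactly when there are few (C(6,2) = 15 in
phase 1), making the procedure deterministic. The estimated FDR of a
cutoff δ is `π0 · median_b #{d_perm ≥ δ} / #{d_obs ≥ δ}` with
`π0 = #{d_obs in null IQR}/(m/2)` capped at 1; the smallest observed d
with estimated FDR ≤ 0.05 becomes the cutoff, one-sided for myotube
elevation. With so few distinct relabelings the clone-level guarantee is
necessarily coarse; the insert-level consensus rule (below) absorbs
scattered single-clone false calls, and simulations show an insert-level
null positive rate well under the nominal 0.05 alongside full detection
of 15-fold planted effects at 4 clones.

Phase-1 advancement takes the union of clones with ≥ 2-fold myotube
increase over *both* other cell types (computed on raw averaged ratios;
boundary inclusive) and SAM positives, plus designated control rows.
Phase 2 assesses only myotube vs myoblast. An insert is finally positive
iff at least 2 clones are positive (either phase) and they are at least
50% of the clones with usable data.

## Region properties

Composition profiles count mono- and overlapping dinucleotide frequencies
on the given strand (no reverse-complement symmetrization; exposed as
written), with GC skew `(G−C)/(G+C)` and AT skew `(A−T)/(A+T)`; `N`
bases are dropped first. Set comparisons use two-sided Wilcoxon rank-sum
tests on per-region values.

Conservation summaries report the per-region mean and maximum score; a
region is *conserved* when it has ≥ 20 consecutive bases scoring ≥ 0.7,
while the conserved *make-up* sums maximal runs scoring strictly > 0.7
of any length (the ≥/> asymmetry follows the two published
definitions, which differ). Set-level make-up pools lengths (summed conserved length /
summed region length) rather than averaging per-region fractions,
matching the published summary convention. TSS distance is 0 inside a
region, else the bp gap to the nearest TSS; CpG association means any
island intersects the region ± 1 kb (half-open flank).

TFBS phylogenetic depth: per region set and TF, the mean track score
over retained site footprints is divided by the mean over non-binding
positions (positions outside *every* TF's retained footprint — using
per-TF complements would contaminate the flank mean with other TFs'
elevated sites). TFs with fold ≥ 2 (inclusive) in a responding set form
the selected list, whose fold distributions are compared between sets by
two-sample t-tests. Folds are undefined and the TF skipped when the
non-site mean is not positive, which can occur for phyloP-style tracks;
ratios of signed means are otherwise not interpretable.

## Enrichment and overlap statistics

Fisher tests are exact hypergeometric tails with fixed margins
(`greater` = P(X ≥ a)); enrichment and overlap tests are one-sided in
the direction of excess by default — this choice reproduces every
printed over-representation and overlap p-value to its printed precision
— and overlap outputs report both sides. Degenerate margins give p = 1.
Over-representation results add an oPOSSUM-style Z-score on
nucleotide-level site rates, `(x − np)/√(np(1−p))` with `p` the
background sites-per-nucleotide rate, and rank by Fisher p ascending.
Published Z-scores are not reproducible because the underlying nucleotide
totals are not published. Peak overlap uses a ≥ 1 bp intersection rule
(configurable). ROC curves use midrank tie handling; the AUC equals the
normalized Mann-Whitney U statistic, and the conservation-filtered
variant demotes entries failing the filter to −∞.

## Synthetic data

The generators emulate the screen's study conditions and are fully
deterministic under a fixed seed:

* **Genome** (default 100 kb): i.i.d. background at GC 0.51 with 20
  planted, non-overlapping 200 bp CRMs whose local GC is raised by 0.03
  (the responder 0.54 vs non-responder 0.51 contrast) and which carry 3
  non-overlapping sites drawn from the motif models (rejection-sampled to
  relative score ≥ 0.85, random strand). Background chance hits are left
  in place deliberately — they emulate false-positive predictions. The
  bundled motif set consists of *synthetic* consensus-derived stand-ins
  for the five muscle profiles, not measured matrices.
* **Conservation tracks**: phastCons-like background ~ Beta(0.5, 4.5)
  (mean ≈ 0.1) lifted by 0.5 inside CRMs and by 0.5 × 2 over planted
  sites, clipped to [0, 1]; a phyloP-like unbounded track with the same
  lifts over N(0, 0.3) noise, so the site/non-site fold inside CRMs is
  ≈ 2 by construction.
* **Plates**: renilla ~ lognormal(log 5·10⁴, 0.3); firefly = renilla ×
  effect × lognormal(0, 0.3) with effect 15 (the strong-control
  magnitude) in myotubes for planted positives and 1 otherwise; CV 0.3;
  5% transfection failures drawn below the 1000 LRU floor; two phases
  with independent draws.
* **Peaks**: each region overlapped with probability 0.58 (responders)
  vs 0.16 (non-responders), the myotube overlap rates of the published
  comparison, with random flank extension.

What passing tests on these data show: the statistical machinery behaves
correctly under the assumed error model (multiplicative luminescence
noise, i.i.d. composition, independent per-base conservation noise).
What they do not show: robustness to plate-position effects, correlated
biological replicates, alignment-driven conservation structure,
GC-dependent background site rates, or any chromatin-level signal —
real-data performance claims are limited accordingly.

## Problem sizes and orchestration

The default pipeline and the acceptance script run genome-scale-down
simulations (10–100 kb genomes, 5–40 CRMs, 8–12 inserts × 4 clones,
200 permutations, 20–100 seeded replicates per behavioral check) —
sizes chosen so the full statistical behavior (power, null rates, AUC
gains) is measurable with tight Monte-Carlo error while the whole suite
completes in well under a minute per component. The `crmkit` CLI is a
thin layer over the library: every stage reads and writes plain text
files, records SHA-256 hashes in a provenance log with the embedded
configuration, and regenerates byte-identical outputs under the same
seed.
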