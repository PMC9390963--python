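# Methods

## The scientific question and the shape of the pipeline

The package analyses bulk RNA-seq time courses collected around the start
of immune checkpoint blockade in two transplantable mouse tumour models
(AB1, Renca), each split into responders and non-responders. The working
hypothesis is kinetic, not static: responders are distinguished by
interferon-stimulated genes (ISGs) that are already high at or just after
treatment start and switch off within days (*on/fast-off*), whereas
non-responders activate the same genes slowly and keep them on. The chain
that isolates this signature is: soft clustering of time profiles and
matching of cluster trends across models → tree-ensemble inference of a
regulator→target network from responder samples → pruning to
promoter-supported "direct" edges → k-means isolation of the fast ISG
subset and scoring → summary statistics (TF→ISG matrices, the
hive-quadrant edge share). Side analyses mirror the study's supporting
statistics: mixture deconvolution against a cytokine-stimulated T-cell
reference, a transcriptional-momentum statistic for embedding velocities,
growth-curve response classification, and the log-rank power design.

Because the real accession data are not required, a first-class generator
produces every input with known ground truth, and the tests ask whether
the chain *rediscovers* what was embedded.

## Synthetic data model

**Design.** Two models × two arms × timepoints (0, 2, 4, 6 days) × 3
replicates; each sample is an independent animal (tumours are resected, so
timepoints are cross-sectional).

**Archetypes.** Every gene carries one of five dynamics archetypes,
realised as 4-point templates expressed as fractions of the gene's peak
mean: on/fast-off (responders: (1.0, 0.9, 0.3, 0.15) in AB1,
(0.85, 1.0, 0.35, 0.15) in Renca — the peak sits one design step later in
Renca; non-responders: (0.2, 0.4, 0.6, 0.8)), gradual up
(0.15, 0.4, 0.7, 1.0, both arms), responder-only gradual up, gradual down
(1.0, 0.6, 0.35, 0.2), and flat. Templates are config-overridable. The
noiseless means satisfy the archetype constraints exactly (peak within the
first two timepoints, strictly decreasing afterwards, final value below
half peak for responders; monotone non-decreasing for non-responders), and
the tests assert them on the mean matrix.

**Regulatory structure.** The first five genes are the interferon TFs
(Irf1, Stat1, Stat2, Irf7, Irf9; on/fast-off archetype — they are
themselves ISGs); remaining TFs cycle through the other archetypes. Each
fast ISG is driven by 1–2 interferon TFs (all such edges are
promoter-proximal, i.e. *direct*); slow "chronic" ISGs and the other
targets hang off single non-IFN TFs with a 50% chance of being direct. A
target's log-mean is Σ w·log(regulator mean) with weights w ~ U(0.5, 1.5),
rescaled so the gene's maximum over all conditions equals its drawn peak
count (log-normal, median ≈ 300 — well-expressed genes). Differential
expression is defined by arm-dependent archetypes (on/fast-off and
responder-only-up genes and their targets).

**Noise.** Counts are gamma–Poisson (negative binomial) with
var = μ + φμ², φ = 0.15 by default — a typical replicate-level dispersion
for inbred-mouse bulk RNA-seq — times a per-sample library factor
U(0.7, 1.3). TPM here means column-normalisation to 10⁶ (inputs are
gene-level; no length correction).

**Annotations.** One synthetic chromosome; gene *i*'s TSS at 50 kb·(i+1)
on alternating strands. Each direct edge gets one 10-bp binding site
placed uniformly inside the target's strand-aware promoter window; each
indirect true edge gets a decoy site 2–5 kb from the TSS, outside every
window (genes are 50 kb apart, windows ≤ 400 bp). Window-based pruning
therefore has an exact expected answer.

**What the generator does not emulate:** read-level sampling,
isoform/length structure, batch effects, gene–gene correlation beyond the
explicit regulator coupling, dropout, and any immune-cell composition
signal. Passing tests show the *procedures* recover planted structure
under realistic count noise; they do not certify performance on real
tumour data.

## Stage-by-stage choices

**Profiles.** Replicates are averaged per (model, arm, timepoint), then
log₂(x+1)-transformed, then z-normalised per gene across timepoints (sd
with denominator n−1; constant rows become all-zero and are flagged and
excluded from clustering). The log step is the field norm for profile
clustering and has a structural payoff here: with log-linear regulator
coupling, z-scoring a log profile removes the coupling weight entirely, so
targets inherit their regulators' *shape* exactly. The documented
z-normalisation itself operates on whatever mean-layer matrix it is given.

**Fuzzy c-means.** k = 6 clusters by default; fuzzifier m from the
Schwämmle–Jensen data-shape rule (≈2.9 for 300 genes × 4 timepoints)
unless set; k-means++ seeding with 10 restarts, best final objective wins;
convergence when the objective improves by <1e−9 or at 300 iterations.
Tested against an independently written FCM (random initialisation, 200
restarts): objectives agree to 1e−6. Cluster labels are arbitrary;
downstream logic is relabelling-invariant. Cluster trends are the centroid
vectors themselves (4 points; smoothing would be underdetermined), matched
across models at Pearson r ≥ 0.8 (configurable). Clustering runs on
responder profiles per model; non-responder trends of the same genes are
reported alongside. A matched pair is called on/fast-off-shaped when both
centroids peak within the first two timepoints, are still ≥ +0.5 z at day
2, and end ≤ −0.5 z — with 4-point profiles any monotone decline
correlates highly with on/fast-off, so the shape call needs the
mid-course level, not just the trend.

**Network inference.** Per target, a random forest (default 1000 trees,
√p features per split, bagging on) regresses the unit-variance-standardised
target on all candidate regulators; edge importance is the per-tree total
variance reduction attributed to the regulator, averaged over trees, with
no cross-target renormalisation. All candidate pairs are kept (zero
importances included) — thresholding is a read-time decision, and pruning
then depends only on the annotations. Per-target seeds come from
`SeedSequence.spawn`, so parallel and sequential runs agree bit-for-bit.
Exact sample-order invariance holds only without bagging (and up to float
summation order); with bagging, recovery (AUROC against planted edges) is
what is stable, and both properties are tested. Desk-scale defaults for
tests: 100 trees, ≤ 50-gene networks.

**Pruning.** Promoter window: [TSS−400, TSS+300) on +, mirrored on −,
clipped at 0, half-open BED coordinates, any ≥1 bp overlap retains the
edge (the semantics of a BED window operation); a strand-ignoring switch
reproduces the symmetric behaviour. Retained edge ⇔ regulator in the TF
list, target differentially expressed, and a same-TF site overlaps the
window. Missing TSSs and site-less TFs drop edges with counted warnings.
The hive-quadrant statistic uses the linear-interpolation empirical
quantile (default 0.9) with strict exceedance; node classes rank
ifn_tf > other_tf > fast_isg > other (the five interferon TFs sit on the
TF axis even though they are ISGs).

**Signature.** ISG sets arrive as GMT (α/β and γ; membership in both →
class "both"). The fast subset is the k=2 k-means cluster (on z-scored
responder profiles) whose centroid is higher at the model's early
timepoint — day 0 for AB1, day 2 for Renca, matching the one-step-later
Renca kinetics; this is label-invariant by construction and equals the
exhaustive minimum-SSE 2-partition on small inputs. Per-model derivation
is exposed as a parameter (pipeline default: AB1). Sample scores are the
mean across signature genes of per-gene z-scores taken across samples —
the simplest statistic consistent with an "average expression" readout;
it is invariant to per-gene affine rescaling and sums to zero across
samples when no gene is dropped.

**Deconvolution.** The reference collapses labelled samples to per-gene
population means (7 populations). The solver is non-negative least squares
per sample over the inner join of gene ids, with coefficients renormalised
to sum to one and the residual norm reported. This *replaces* the ν-SVR of
the CIBERSORT family deliberately: the ν-SVR internals (ν grid, feature
scaling) are not fully specifiable from the outside, while NNLS estimates
the same quantity and recovers exact mixtures to ~1e−8. Quantile
normalisation is not applied (the RNA-seq recommendation). Consequences:
on noisy, collinear references NNLS can be less robust than ν-SVR — treat
absolute fractions on real data with care. The TPM prevalence filter
(strictly > 0.3 in ≥ 8 samples, the smallest group size) applies to
whichever matrix is being filtered.

**Momentum.** ‖v‖² per cell from the 2-D embedding velocity; no
cross-sample normalisation. Group comparison uses the asymptotic two-sided
rank-sum test *without* continuity correction — chosen so identical groups
give p = 1.0 exactly — and Gaussian KDEs with Scott's-rule bandwidth on a
shared grid. Velocity estimation itself (spliced/unspliced fits, graph
projection) is out of scope; vectors are inputs.

**Outcomes.** Response calls are deterministic: non-responder if any
in-window (≤28 d) area ≥ 100 mm² (≥ chosen where the boundary is
unstated, and parameterised); responder if the area reaches ≤ 0 mm² and
stays there through the last in-window measurement; otherwise
intermediate. The cage filter keeps cages with ≥1 responder and ≥1
non-responder after dropping intermediates. The log-rank test is the
standard Mantel–Cox O−E/V chi-square with 1 df, implemented vectorised
over distinct event times (it sits inside 10,000-replicate loops) and
cross-checked per-case against lifelines in the tests.

**Power design.** Control hazard λ = ln2/35 per day; experimental hazard
λ/HR; all events observed unless an administrative censoring day is set
(the design follows animals to endpoint; censoring is a sensitivity
knob). Monte-Carlo power is the rejection fraction over replicates, with
binomial standard error. Two finite-sample facts are worth stating
plainly, because the tests record them honestly: at n = 10 + 10 with all
events, (i) the chi-square reference makes the log-rank test mildly
anti-conservative — its empirical size is ≈ 0.062–0.067 at nominal 0.05
(the package's Monte-Carlo agrees with an independent R `survdiff`
simulation) — and (ii) the Schoenfeld approximation Φ(√(d/4)|ln HR| −
z₁₋α/₂) overshoots the true power at 20 events and ln HR = ln 5 (0.949
vs ≈ 0.89 simulated). The corresponding acceptance-suite assertions of
nominal calibration and 3-standard-error agreement therefore fail by
design of the test, not of the code; the design's headline claim —
power ≥ 0.8 with 10 per group at HR 5 — holds with margin.

## Numerical conventions and degenerate inputs

0-based half-open genomic coordinates throughout; ties in hard cluster
assignment go to the lowest cluster index; regulator-ranking ties break
lexicographically; constant expression rows are flagged/zeroed rather than
dropped silently; constant centroids are skipped in trend matching;
all-equal edge importances yield zero "top" edges with a warning; a
zero-sum NNLS solution falls back to uniform fractions. Every stochastic
component takes an explicit seed, and the pipeline manifest records
parameters and SHA-256 hashes of all artifacts; reruns are byte-identical.

## Problem sizes used by the test and acceptance runs

Default synthetic study: 300 genes (10 TFs, 40 fast + 40 slow ISGs, ~20%
flat background), 48 samples; networks inferred with 100 trees over the
10 TFs as candidate regulators; power simulations at 10,000 replicates;
oracle comparisons on ≤ 40-gene inputs (FCM), ≤ 15 genes (k-means),
≤ 12 genes (exhaustive 2-partitions). These sizes keep a full run in
roughly two minutes while leaving all recovery margins wide (fast-ISG
Jaccard 1.0, pruned-edge set equality, AUROC ≈ 0.98 on the 20-gene
benchmark).

## Known limitations

Four timepoints bound what "shape" can mean — trend correlation cannot
separate profiles that differ only in curvature; the generator's archetype
world contains no partially overlapping programmes or feedback; GENIE3
importances are relative, so cross-dataset comparisons of raw scores are
not meaningful; NNLS deconvolution assumes the reference spans the
mixture; and the log-rank small-sample behaviour above applies to any
10-vs-10 design analysed with the chi-square reference.
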