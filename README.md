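# onoffgrn

Tools for asking a dynamics question of checkpoint-blockade time courses:
**is response to immune checkpoint blockade (ICB) marked by *on/fast-off*
interferon kinetics?** In two mouse tumour models (AB1 mesothelioma, Renca
renal cell carcinoma) sampled at days 0/2/4/6 around ICB start,
responders show interferon-stimulated genes (ISGs) that are high at or just
after treatment start and shut down within days, while non-responders show
a slow chronic rise. This package implements the full analysis chain that
isolates that signature — driven end-to-end by a synthetic-data generator
with embedded ground truth, so every stage is testable without any
download.

## What it does

1. **Synthetic study generator** (`onoffgrn.synthetic`) — negative-binomial
   time-course counts for a 2-model × 2-arm × 4-timepoint design with an
   embedded TF→target network and five dynamics archetypes (on/fast-off,
   gradual up, responder-only up, gradual down, flat); matching TSS/TFBS
   annotations on a synthetic chromosome; cytokine-reference mixtures;
   tumour growth curves; exponential survival; velocity embeddings.
2. **Time-course clustering** (`onoffgrn.clustering`) — replicate
   averaging, log₂, per-gene z-normalisation, fuzzy c-means
   (memberships `u_gc ∝ (1/d²)^{1/(m−1)}`, centroids `Σu^m x / Σu^m`,
   fuzzifier from the Schwämmle–Jensen rule), and cross-model cluster
   matching by Pearson correlation of centroid trends.
3. **Network inference** (`onoffgrn.grn`) — GENIE3-style random-forest
   regression per target (k = √p features per split, 1000 trees by
   default); edge importance = per-tree variance reduction averaged over
   trees; regulators ranked by summed outgoing importance; k-means (k=4)
   modules of regulator profiles.
4. **Direct-edge pruning** (`onoffgrn.direct`) — keep TF→gene edges only
   when the differentially expressed target carries a binding site for the
   TF within 400 bp upstream / 300 bp downstream of its TSS
   (strand-aware, BED half-open, ≥1 bp overlap); TF→ISG score matrices;
   hive-quadrant statistic (share of >0.9-quantile edges running from
   IFN-related TFs — Irf1, Stat1, Stat2, Irf7, Irf9 — to fast ISGs).
5. **IFN signature** (`onoffgrn.signature`) — assemble α/β + γ ISG sets
   from GMT, derive the fast-on/off subset by k-means (k=2) on responder
   profiles (the cluster higher at day 0 in AB1 / day 2 in Renca is
   "fast"), and score samples by mean z across signature genes.
6. **Deconvolution** (`onoffgrn.deconvolution`) — collapse labelled
   samples into a 7-population cytokine reference (IFNβ, Resting, Th17,
   Th2, Th1, Th0, iTreg), filter genes at TPM > 0.3 in ≥ 8 samples, and
   estimate mixture fractions by non-negative least squares with
   sum-to-one renormalisation.
7. **Velocity momentum** (`onoffgrn.momentum`) — per-cell transcriptional
   momentum ‖v‖² from 2-D embedding velocity vectors; rank tests and KDE
   comparisons between groups.
8. **Outcomes & power** (`onoffgrn.outcomes`) — growth-curve response
   calls (complete regression sustained 4 weeks = responder; ≥100 mm²
   within 4 weeks = non-responder; otherwise intermediate, excluded), the
   cage dichotomy filter, a two-group log-rank (Mantel–Cox) test, and the
   study's survival power design (exponential survival, control median
   35 d, hazard ratio 5, n = 10/group, α = 0.05), with the Schoenfeld
   closed form Φ(√(d/4)·|ln HR| − z₁₋α/₂) as analytic companion.

The fit/transform-shaped pieces are scikit-learn-style estimators —
`FuzzyCMeans`, `TreeEnsembleGRN`, `NNLSDeconvolver` — with
`get_params`/`set_params` and trailing-underscore fitted attributes; the
module-level functions are thin wrappers around them.

## Worked example

Run the whole chain on the default synthetic configuration (~300 genes,
10 TFs, 3 replicates per condition, seed 0):

```sh
onoffgrn run --out run/
```

`run/report.json` then contains (values printed by this exact command):

```
n_fast = 45                    # derived fast-on/off ISGs
jaccard_fast_vs_truth = 1.0    # perfect recovery of the embedded fast set
hive:
  AB1:   threshold 0.0092, 9 top edges, 0.778 in the IFN-TF -> fast-ISG quadrant
  Renca: threshold 0.0184, 9 top edges, 1.000 in the IFN-TF -> fast-ISG quadrant
```

Reading: the k=2 split of the ISG profiles recovers exactly the 45 genes
simulated with on/fast-off dynamics, and the strongest edges of the pruned
regulatory networks concentrate in the IFN-TF → fast-ISG quadrant — the
synthetic analogue of the dominance of interferon regulators over the fast
ISG module. The same directory holds the count matrix, cluster
memberships/centroids, inferred and pruned edge lists, and a manifest with
a SHA-256 per artifact (reruns are byte-identical).

The survival design, from the shell:

```sh
onoffgrn power --hr 5 --n 10 --reps 10000 --seed 1
# {"mc_se": 0.0030, "power_estimate": 0.8998, "reps": 10000, "schoenfeld": 0.9494}
```

Ten mice per group give ~90% Monte-Carlo power at a true hazard ratio of 5
— comfortably above the 80% design point. (The Schoenfeld approximation
overshoots at only 20 events; see `docs/methods.md`.)

## Layout

```
src/onoffgrn/     synthetic.py clustering.py grn.py direct.py signature.py
                  deconvolution.py momentum.py outcomes.py io.py pipeline.py cli.py
tests/            unit + property tests per module, oracle implementations,
                  acceptance suite
docs/methods.md   model, assumptions, parameter choices, limitations
scripts/          acceptance.py
```
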