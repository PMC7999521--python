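# Methods

## Problem and model

`enterotyper` stratifies a cohort of gut-microbiome samples into
*enterotypes* (ETs) — discrete community-composition types — from a
genus-level relative-abundance table, and then asks how those strata
relate to intestinal butyrate production: fecal butyrate concentration
(mg/g fresh feces) and the abundances of the two terminal
butyrate-synthesis genes, butyrate kinase (*Buk*) and
butyryl-CoA:acetate-CoA transferase (*But*), measured as log10 gene
copies per gram.

The analysis chain is:

1. **Distance.** Each sample is a composition p over genera.  Pairwise
   dissimilarity is the root Jensen–Shannon divergence
   `D(p,q) = sqrt(JSD(p,q))` with `JSD = ½KL(p‖m) + ½KL(q‖m)`,
   `m = (p+q)/2`, natural logarithms.  D is a metric bounded by
   `sqrt(ln 2) ≈ 0.8326`.  Zero entries are replaced by a pseudo-count
   (default `1e-9`, applied per profile, then re-normalized), so
   identical profiles sit at distance exactly 0.  The log base and zero
   handling are recorded in the run manifest because they change
   silhouette/PS values bit-for-bit.
2. **Clustering.** Partitioning Around Medoids (k-medoids) on the
   precomputed distance matrix, minimizing the *sum* of distances to
   medoids.  BUILD greedily seeds medoids; SWAP repeatedly applies the
   single best cost-decreasing medoid↔non-medoid exchange.  All ties
   break toward the lowest sample index, so runs are deterministic.  On
   small instances (n ≤ 16) the SWAP descent is restarted from a BUILD
   anchored at every sample and the best solution kept: single-start
   BUILD+SWAP provably stalls in local optima on a few percent of tiny
   instances (the R `cluster::pam` default stalls on the same ones), and
   the multi-start descent removes that failure mode while staying
   deterministic.  Clusters are renumbered by decreasing size (ties:
   lower medoid index), so "ET1" is always the largest stratum.
3. **Number of clusters.** Two criteria over a K range (default 2–6):
   the **silhouette index** `SI = mean (b−a)/max(a,b)` (singletons score
   0), and the **prediction strength** `PS(K)`: split samples 50/50 at
   random, cluster both halves independently, classify the test half
   onto the training medoids, and take the minimum over test clusters of
   the fraction of within-cluster pairs co-assigned by that
   classification (test clusters of size < 2 are excluded; `PS(1) = 1`).
   PS is averaged over 20 random splits.  The chosen K maximizes SI
   among K with mean PS ≥ 0.8 (the published guidance range for PS is
   0.8–0.9; the permissive end suits n ≈ 105, since each half holds only
   ~52 samples).  If no K clears the threshold the SI maximizer is
   returned with an explicit warning flag.
4. **Ordination.** Classical PCoA: Gower double-centering of −½D²,
   eigendecomposition, coordinates scaled by sqrt(eigenvalue).  Root-JSD
   is a metric but not always Euclidean-embeddable; negative eigenvalues
   are dropped (no Lingoes/Cailliez correction, matching common ecology
   defaults) and their magnitudes reported.  Axis signs are fixed by
   making each axis's largest-magnitude coordinate positive, so
   ordinations are bit-stable.
5. **Statistics.** Kruskal–Wallis (chi-square approximation, mid-rank tie
   correction) compares every feature among ETs; raw p-values are
   reported together with Benjamini–Hochberg q-values within each
   feature family (taxa / alpha-diversity / phenotype) — the q-values
   are an addition, not a replacement of the raw p convention.  Compact
   letter displays come from all pairwise two-sided Mann–Whitney tests,
   BH-corrected within a feature, with a greedy insert-and-absorb letter
   assignment; groups sharing a letter did not differ at α = 0.05.
   Spearman correlations (Pearson on mid-ranks, tie-safe) describe
   genus co-occurrence among the top-N most abundant genera (default 12)
   and rank candidate butyrate-producer genera by their correlation with
   butyrate and with the *Buk*/*But* copy numbers (log10 scale, as
   stored).  Group tables report both means and medians per ET, since
   "group value" conventions differ across publications.

## Synthetic cohorts

The generator emulates the processed data of a ~105-sample pig cohort so
the whole pipeline can be exercised without any sequencing data.

* **Composition.** 40 taxa: 39 named swine-gut genera plus an
  `unclassified` bin (genus-level 16S tables always carry one; it absorbs
  each component's unclaimed mass).  Three component mean profiles plant
  the driver genera at the emulated cohort's per-ET mean abundances
  (ET1 *Lactobacillus* 14.39% / *Clostridium sensu stricto 1* 13.41%;
  ET2 *Clostridium sensu stricto 1* 17.49% / *Bifidobacterium* 11.78%;
  ET3 *Bacteroides* 18.17%) and shape the remaining genera after the
  emulated cohort's per-ET phylum composition (Actinobacteria, Proteobacteria and
  Acidobacteria enriched in ET2; Bacteroidetes in ET3; Spirochaetes and
  the Firmicutes surplus in ET1).  Six butyrate producers
  (*Faecalibacterium*, *Butyricicoccus*, *Eubacterium hallii group*,
  *Butyricimonas*, *Blautia*, *Anaerostipes*) are elevated in component
  3 in that order.
* **Sampling.** Per sample: component ~ Multinomial(mixing, default
  1/3 each); proportions ~ Dirichlet(concentration × component profile);
  counts ~ Multinomial(depth) with depth log-uniform in
  [40,000, 100,000] (echoing the emulated per-sample read range).  A
  shared lognormal factor (σ = 0.3) scales the *Clostridium sensu
  stricto 1* / *Turicibacter* / *Romboutsia* trio together, planting
  their co-occurrence.
* **Concentration = 300.** The clustering problem should be nontrivial
  but solvable: at 300 the between-component root-JSD (0.27–0.44) is
  ≈ 2–3.6× the within-component spread (~0.12), i.e. about 3× on
  average.  Looser dispersion (e.g. concentration ≤ 100) makes the
  within-component spread exceed the closest between-component distance,
  and no clustering method could recover the planted K — a geometry that
  would say nothing about the pipeline.
* **Phenotype.** butyrate = 0.6 + Σ slope_g · relabund_g + N(0, 0.35),
  truncated at 0, with slopes 50/14/10/7/4/2 (mg/g per unit relative
  abundance) for the six producers.  The steep ladder makes the realized
  taxon–butyrate Spearman correlations span ~0.3–0.9 with
  *Faecalibacterium* on top, mirroring the correlation spread of the
  cohort the generator emulates; the three non-planted producer genera
  (*Coprococcus*, *Oscillospira*, *Roseburia*) come out near 0.
* **Gene copies.** log10 copies are built from the butyrate ranks via
  normal scores: `y = μ + σ(r·z + sqrt(1−r²)·ε)` with
  `r = 2 sin(π·ρ_target/6)`, so the realized Spearman correlation with
  butyrate approaches the configured targets — defaults ρ = 0.7464
  (*But*) and 0.4905 (*Buk*), the coupling strengths of the emulated cohort.  Across 20
  cohorts the realized couplings average ~0.75 and ~0.50 with ±0.08
  per-cohort sampling spread.
* **Null cohort.** One mixed component, no producer slopes, no shared
  latent factor: phenotype independent of all taxa (gene copies stay
  coupled to butyrate).  Used as the negative control for K selection
  and for type-I calibration of the group tests.

What the generator does **not** emulate: the real cohort's 1178-genus
tail (40 taxa suffice for the clustering geometry but understate
rare-taxon sparsity), depth–composition coupling, overdispersion beyond
Dirichlet-multinomial (no zero inflation), and any host covariate
structure (physicochemical covariates are generated independent of
everything, as the emulated study found no ET differences in them).
Passing tests therefore demonstrate correctness of the algorithms and
recoverability under a realistic compositional model — not performance
on real 16S data.

## Numerical choices and degenerate inputs

* Ties: everywhere toward the lowest index (medoid assignment, swap
  selection, letter ordering), making runs bit-reproducible.
* All-identical values in a group test: H = 0, p = 1 (scipy would
  reject); constant taxa in the co-occurrence matrix keep a flagged NaN
  row rather than being dropped.
* Relative tables must row-sum to 1 within 1e-9; normalization leaves
  rows already within 1e-12 of 1 untouched, so it is exactly idempotent.
* `zero_replacement = 1e-9` perturbs distances by < 1e-6 while keeping
  identical profiles at exactly 0 and padding-with-zero-taxa harmless.
* PCoA eigenvalues below `max|λ|·1e-10` are treated as zero.
* All randomness (generator, PS splits, optional PAM restarts) flows
  from explicit integer seeds recorded in the run manifest.

## Problem sizes used in validation

The test-suite and the acceptance script work at the study's own scale —
105 samples × 40 genera, K selection over 2–6 with 20 prediction-strength
repeats — repeated over 20–40 independently seeded cohorts for the
recovery-rate checks; small synthetic instances (n ≤ 16) are used where
an exhaustive-search oracle must stay cheap.

## Known limitations

* Spearman co-occurrence on compositions is not compositionality-aware
  (no SparCC/SPIEC-EASI); closure effects can induce negative bias.
* PS with 50/50 splits is noisy below ~60 samples; the default K range
  caps at n/2 for this reason.
* The compact-letter display depends on the post-hoc test chosen
  (pairwise Mann–Whitney here); other choices can merge or split letter
  groups near α.
* BIOM support is limited to dense JSON v1.0; HDF5 BIOM is out of scope.
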