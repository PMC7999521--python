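# enterotyper

Enterotype discovery and butyrate-association analysis for genus-level
16S abundance tables.

Gut microbiomes of pigs (and humans) stratify into a small number of
discrete community types — *enterotypes* (ETs) — driven by dominant
genera such as *Lactobacillus*, *Clostridium sensu stricto 1* and
*Bacteroides*.  Because butyrate-producing genera are unevenly
distributed across these strata, enterotype membership carries over into
intestinal butyrate production.  `enterotyper` packages that analysis as
a tested, reusable pipeline for anyone with a samples × genera abundance
table and per-sample phenotype measurements:

* **Enterotyping** — root Jensen–Shannon divergence
  `D(p,q) = sqrt(½KL(p‖m) + ½KL(q‖m))`, `m = (p+q)/2`, between
  per-sample genus profiles; Partitioning Around Medoids (PAM) on the
  distance matrix; the number of clusters K chosen by prediction
  strength (PS ≥ 0.8) and silhouette index (SI), with
  principal-coordinates analysis (PCoA) for visualization and per-sample
  alpha diversity (observed taxa, Shannon H).
* **Group statistics** — Kruskal–Wallis tests of every taxon,
  diversity metric and phenotype among ETs with BH q-values and compact
  letter displays; Spearman co-occurrence among the most abundant
  genera.
* **Butyrate association** — Spearman rank correlations ρ between
  candidate butyrate-producer genera, fecal butyrate (mg/g), and the
  log10 copy numbers of the terminal butyrate-synthesis genes *Buk*
  (butyrate kinase) and *But* (butyryl-CoA:acetate-CoA transferase),
  ranked exactly like the field's producer tables.
* **Synthetic cohorts** — a Dirichlet-multinomial generator that plants
  three enterotypes with realistic driver-genus abundances and a
  butyrate phenotype coupled to producer genera (*But* more strongly
  than *Buk*), so every stage is testable end to end without sequencing
  data.

## Worked example

```python
import enterotyper as et

cfg = et.default_config(seed=7)                 # 105 samples, 3 planted ETs
table, phenotype, truth = et.generate_cohort(cfg)
rel = et.normalize_relative(table)
dm = et.jsd_matrix(rel)

report = et.choose_k(dm, k_range=range(2, 7), seed=7)
print(report.to_frame().round(3))
```

```
   silhouette  prediction_strength  chosen
K
2       0.447                0.785   False
3       0.470                1.000    True
4       0.330                0.571   False
5       0.185                0.465   False
6       0.042                0.417   False
```

K = 2 narrowly fails the PS ≥ 0.8 stability bar and K = 3 — the planted
number — wins on both criteria: perfectly stable under cross-validation
(PS = 1.0) with the best silhouette (0.470).  Clustering at the chosen K
and ranking producer genera against the butyrate phenotype:

```python
result = et.pam(dm, report.chosen_k)
ranking = et.phenotype_association_ranking(
    rel, phenotype, ["Faecalibacterium", "Butyricicoccus", "Blautia"])
print(ranking.table[["rho_butyrate", "rho_buk", "rho_but"]].round(4))
print({g: round(v["rho"], 4) for g, v in ranking.gene_correlations.items()})
```

```
                  rho_butyrate  rho_buk  rho_but
taxon
Faecalibacterium        0.8005   0.2480   0.5935
Butyricicoccus          0.6763   0.2669   0.5951
Blautia                 0.4188   0.0992   0.3861
{'buk': 0.4364, 'but': 0.7899}
```

*Faecalibacterium* heads the producer ranking (ρ = 0.80 with fecal
butyrate), and butyrate correlates much more strongly with *But* copies
(ρ = 0.79) than with *Buk* (ρ = 0.44) — the pipeline recovers both
planted relationships.

The same analysis runs from the shell:

```bash
enterotyper simulate --seed 7 --out cohort/
enterotyper enterotype --table cohort/abundance.tsv --k-range 2 6 --out et/
enterotyper associate --table cohort/abundance.tsv \
    --phenotype cohort/phenotype.tsv --labels et/labels.tsv --out assoc/
```

Each stage writes TSV artifacts (`ksel.tsv`, `labels.tsv`, `pcoa.tsv`,
`group_tests_*.tsv`, `cooccurrence.tsv`, `butyrate_ranking.tsv`) plus a
`manifest.json` recording every parameter, seed and input digest; output
directories are written atomically.

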